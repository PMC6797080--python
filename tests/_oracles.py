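"""Independent brute-force oracles used only by the test suite.

Each oracle deliberately re-derives a quantity from first principles and
shares no code path with the package implementation it checks:

* d-separation by exhaustive path enumeration and the textbook blocking
  rules;
* least squares via the normal equations;
* probit log-likelihood refit via generic numerical optimization;
* marginal effects via finite differences of predicted probabilities.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm


# ---------------------------------------------------------------------------
# d-separation by path enumeration


def latent_expand(nodes, directed, bidirected):
    nodes = set(nodes)
    directed = set(map(tuple, directed))
    for i, (a, b) in enumerate(sorted(tuple(sorted(p)) for p in bidirected)):
        lat = f"__oracle_latent_{i}"
        nodes.add(lat)
        directed.add((lat, a))
        directed.add((lat, b))
    return nodes, directed


def _descendants(directed, node):
    children = {}
    for a, b in directed:
        children.setdefault(a, set()).add(b)
    seen, stack = set(), [node]
    while stack:
        n = stack.pop()
        for c in children.get(n, ()):
            if c not in seen:
                seen.add(c)
                stack.append(c)
    return seen


def _all_paths(nodes, directed, x, y):
    """Every simple path between x and y ignoring edge direction, kept as a
    list of (node, arrived_via_incoming_arrow?) steps."""
    neighbors = {}
    for a, b in directed:
        neighbors.setdefault(a, []).append((b, "out"))  # a -> b leaving a
        neighbors.setdefault(b, []).append((a, "in"))  # arrive a from b against arrow
    paths = []

    def walk(node, visited, path):
        if node == y:
            paths.append(list(path))
            return
        for nxt, direction in neighbors.get(node, ()):
            if nxt in visited:
                continue
            # direction is relative to the edge as stored: moving node->nxt
            # along a->b means nxt entered via an incoming arrow iff the edge
            # points toward nxt.
            into_next = direction == "out"
            path.append((nxt, into_next))
            walk(nxt, visited | {nxt}, path)
            path.pop()

    walk(x, {x}, [])
    return paths


def path_blocked(path, directed, z, x):
    """Textbook blocking rules for one path from x (steps exclude x)."""
    # reconstruct arrow orientation at every interior node
    full = [(x, None)] + path
    for i in range(1, len(full) - 1):
        node, entered_via_arrow = full[i]
        next_entered_via_arrow = full[i + 1][1]
        is_collider = entered_via_arrow and not _leaves_via_arrow(full, i)
        if is_collider:
            desc = _descendants(directed, node) | {node}
            if not (desc & z):
                return True
        else:
            if node in z:
                return True
    return False


def _leaves_via_arrow(full, i):
    """True if the edge from full[i] to full[i+1] points away from full[i]."""
    return full[i + 1][1]  # next node entered via an incoming arrow


def d_separated_bruteforce(nodes, directed, bidirected, x, y, z):
    """True iff every (latent-expanded) path between x and y is blocked."""
    nodes, directed = latent_expand(nodes, directed, bidirected)
    z = set(z)
    for path in _all_paths(nodes, directed, x, y):
        if not path_blocked(path, directed, z, x):
            return False
    return True


def random_dag(rng, max_nodes=8, p_edge=0.35, p_bidirected=0.15):
    """Seeded random DAG over letters; edges only forward in a shuffled
    topological order, so acyclicity holds by construction."""
    n = int(rng.integers(3, max_nodes + 1))
    names = [f"N{i}" for i in range(n)]
    order = list(rng.permutation(names))
    directed = []
    for i, j in itertools.combinations(range(n), 2):
        if rng.random() < p_edge:
            directed.append((order[i], order[j]))
    bidirected = []
    for a, b in itertools.combinations(names, 2):
        if rng.random() < p_bidirected:
            bidirected.append((a, b))
    return names, directed, bidirected


# ---------------------------------------------------------------------------
# regression oracles


def ols_normal_equations(y, X):
    """Coefficients via the normal equations (pseudo-inverse)."""
    return np.linalg.pinv(X.T @ X) @ (X.T @ y)


def probit_refit(y, X, start=None):
    """Independent probit fit: generic BFGS on the log-likelihood."""

    def negll(beta):
        xb = X @ beta
        ll = y * norm.logcdf(xb) + (1 - y) * norm.logcdf(-xb)
        return -ll.sum()

    def grad(beta):
        xb = X @ beta
        lam = norm.pdf(xb) * (y - norm.cdf(xb)) / (norm.cdf(xb) * norm.cdf(-xb))
        return -(X * lam[:, None]).sum(axis=0)

    beta0 = np.zeros(X.shape[1]) if start is None else start
    res = minimize(negll, beta0, jac=grad, method="BFGS",
                   options={"gtol": 1e-10, "maxiter": 500})
    return res.x


def probit_ame_finite_difference(beta, X, j, delta=1e-6):
    """AME of column j by finite differences of predicted probabilities."""
    hi = X.copy()
    hi[:, j] = hi[:, j] + delta
    p1 = norm.cdf(hi @ beta)
    p0 = norm.cdf(X @ beta)
    return float(np.mean((p1 - p0) / delta))


def probit_ame_discrete(beta, X, j):
    """Discrete 0→1 probability contrast for a binary column j."""
    hi = X.copy()
    lo = X.copy()
    hi[:, j] = 1.0
    lo[:, j] = 0.0
    return float(np.mean(norm.cdf(hi @ beta) - norm.cdf(lo @ beta)))


# ---------------------------------------------------------------------------
# analytic omitted-variable bias for the negative control


def omitted_baseline_ovb():
    """Analytic relative bias of the follow-up-score OLS when the baseline
    score Y1 (and with it V3) is omitted, at the default coefficients.

    Uses the Gaussian threshold identity Cov(G, 1{S>0}) = Cov(G,S)·φ(μ/σ)/σ
    with the binary strategy decision approximated through its exact mean
    and variance.  The true treatment effect is 1, so this is directly the
    relative bias.
    """
    # strategy decision D2: index 0.3 Z1 + 0.3 Z2 + 0.4 B1 + 0.3 W1 - 0.3 W2 + eps
    sig_sd2 = np.sqrt(0.09 * 4 + 0.16 + 1.0)
    lam_d2 = norm.pdf(0.0) / sig_sd2
    var_d2 = 0.25
    cov_d2 = {"Z1": 0.3 * lam_d2, "X2": 0.5 * 0.3 * lam_d2}

    # perceptions X4/X5 = 0.5 D2 + 0.3 Z1 + 0.3 X1 + 0.3 X2 + e(0.5)
    shared = 0.25 * var_d2 + 0.09 * 3 + 2 * 0.5 * (
        0.3 * cov_d2["Z1"] + 0.3 * cov_d2["X2"]
    )
    var_x4 = shared + 0.25
    cov_x4_x5 = shared
    e_x4 = 0.25
    cov_x4_z1 = 0.5 * cov_d2["Z1"] + 0.3
    cov_x4_x2 = 0.5 * cov_d2["X2"] + 0.3

    # assignment decision T1 index
    w = {"Z1": 0.3, "X2": 0.3, "X3": 0.3, "X4": 0.4, "X5": 0.3,
         "V1": 0.3, "V2": 0.3, "Y1": 0.3}
    var_y1 = 1.09
    mu = w["X4"] * e_x4 + w["X5"] * e_x4 + w["V2"] * 0.5
    var_w = (
        w["X3"] ** 2 + w["V1"] ** 2 + w["V2"] ** 2 * 0.25
        + w["Y1"] ** 2 * var_y1 + w["Z1"] ** 2 + w["X2"] ** 2
        + (w["X4"] ** 2 + w["X5"] ** 2) * var_x4
        + 2 * w["X4"] * w["X5"] * cov_x4_x5
        + 2 * w["Z1"] * (w["X4"] + w["X5"]) * cov_x4_z1
        + 2 * w["X2"] * (w["X4"] + w["X5"]) * cov_x4_x2
    )
    sig_tot = np.sqrt(var_w + 1.0)
    z = mu / sig_tot
    lam = norm.pdf(z) / sig_tot
    p = norm.cdf(z)

    # omitted component of the outcome equation: U = 0.5 Y1 + 0.3 V3
    cov_u_w = 0.5 * w["Y1"] * var_y1 + 0.3 * w["Y1"] * 0.3
    var_t1_resid = p * (1 - p) - (lam * w["V1"]) ** 2 - (lam * w["V2"]) ** 2 * 0.25
    return float(lam * cov_u_w / var_t1_resid)
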