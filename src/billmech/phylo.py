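"""Phylogenetic comparative statistics.

Implements the comparative toolkit used downstream of the biomechanical
solves: Spearman rank correlations (exact permutation null at small n),
phylogenetic generalized least squares (PGLS) under Pagel's lambda
(maximum likelihood, and fixed at 0 or 1), likelihood-ratio tests of the
lambda bounds, Wilcoxon signed-rank tests, a phylogenetic paired t-test,
Brownian-motion trait simulation and Newick tree I/O.

Pagel's lambda multiplies the off-diagonal entries of the phylogenetic
covariance matrix C (shared root-to-MRCA path lengths): lambda = 0 is an
independence (star) model, lambda = 1 the Brownian-motion model.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

__all__ = [
    "Phylogeny",
    "CorrelationResult",
    "PGLSResult",
    "PairedTTestResult",
    "read_newick",
    "write_newick",
    "simulate_yule",
    "simulate_split_clade",
    "bm_simulate",
    "spearman",
    "pgls",
    "wilcoxon_signed_rank",
    "phyl_paired_ttest",
    "run_correlation_suite",
    "validate_comparative_table",
]


class Phylogeny:
    """Rooted tree with branch lengths and its phylogenetic covariance matrix.

    ``C[i, j]`` is the root-to-MRCA path length shared by tips i and j;
    the diagonal holds root-to-tip distances.
    """

    def __init__(self, tree) -> None:
        import dendropy

        if not isinstance(tree, dendropy.Tree):
            raise TypeError("Phylogeny wraps a dendropy.Tree")
        self.tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if any(lbl is None for lbl in labels):
            raise ValueError("all tips must be labelled")
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate tip labels in tree")
        self.tip_labels: list[str] = labels
        self._C: np.ndarray | None = None

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def cov_matrix(self) -> np.ndarray:
        """Phylogenetic covariance matrix in ``tip_labels`` order."""
        if self._C is not None:
            return self._C
        n = self.n_tips
        idx = {lbl: i for i, lbl in enumerate(self.tip_labels)}
        C = np.zeros((n, n))
        # depth of each node below the root; missing/None edge lengths are an error
        depth: dict[int, float] = {}
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                depth[id(node)] = 0.0
            else:
                el = node.edge.length
                if el is None:
                    raise ValueError("tree has edges without branch lengths")
                depth[id(node)] = depth[id(node.parent_node)] + float(el)
        tips_below: dict[int, list[int]] = {}
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                i = idx[node.taxon.label]
                tips_below[id(node)] = [i]
                C[i, i] = depth[id(node)]
            else:
                groups = [tips_below[id(c)] for c in node.child_nodes()]
                d = depth[id(node)]
                for gi in range(len(groups)):
                    for gj in range(gi + 1, len(groups)):
                        for a in groups[gi]:
                            for b in groups[gj]:
                                C[a, b] = C[b, a] = d
                tips_below[id(node)] = [t for g in groups for t in g]
        self._C = C
        return C

    def align(self, data) -> np.ndarray:
        """Return data as an array in tip order; pandas input is label-aligned."""
        if isinstance(data, (pd.Series, pd.DataFrame)):
            if set(data.index) != set(self.tip_labels):
                raise ValueError("data labels do not match the tree's tip labels")
            return np.asarray(data.loc[self.tip_labels], dtype=float)
        arr = np.asarray(data, dtype=float)
        if arr.shape[0] != self.n_tips:
            raise ValueError("data length does not match number of tips")
        return arr


def read_newick(path) -> Phylogeny:
    import dendropy

    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    except dendropy.utility.error.DataParseError as exc:
        raise ValueError(f"malformed Newick file {path}: {exc}") from exc
    phy = Phylogeny(tree)
    phy.cov_matrix()  # validates branch lengths eagerly
    return phy


def write_newick(phylogeny: Phylogeny, path) -> None:
    phylogeny.tree.write(path=str(path), schema="newick", suppress_rooting=True)


def _phylogeny_from_newick_string(s: str) -> Phylogeny:
    import dendropy

    return Phylogeny(dendropy.Tree.get(data=s, schema="newick"))


# ---------------------------------------------------------------------------
# tree and trait simulation


def _yule_newick(labels: list[str], rng: np.random.Generator, height: float) -> str:
    """Pure-birth (Yule) ultrametric subtree as a Newick string of given height."""
    n = len(labels)
    if n == 1:
        return f"{labels[0]}:{height:.10g}"
    # lineage splitting at rate 1 per lineage until n tips exist
    t = 0.0
    active = [(0, 0.0)]  # (node key, birth time)
    tree_nodes: dict[int, dict] = {0: {"birth": 0.0, "children": None}}
    next_id = 1
    while len(active) < n:
        t += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        key, _ = active.pop(i)
        kids = (next_id, next_id + 1)
        next_id += 2
        tree_nodes[key]["children"] = kids
        for k in kids:
            tree_nodes[k] = {"birth": t, "children": None}
            active.append((k, t))
    t_end = t + rng.exponential(1.0 / n)
    scale = height / t_end
    leaf_iter = iter(labels)

    def render(key: int, parent_birth: float) -> str:
        node = tree_nodes[key]
        edge = (node["birth"] - parent_birth) * scale
        if node["children"] is None:
            edge = (t_end - parent_birth) * scale
            return f"{next(leaf_iter)}:{edge:.10g}"
        a, b = node["children"]
        sub = f"({render(a, node['birth'])},{render(b, node['birth'])})"
        return f"{sub}:{edge:.10g}"

    root = tree_nodes[0]
    a, b = root["children"]
    return f"({render(a, 0.0)},{render(b, 0.0)})"


def simulate_yule(n_tips: int, seed: int | np.random.Generator = 0, height: float = 1.0,
                  prefix: str = "sp") -> Phylogeny:
    """Random pure-birth ultrametric tree scaled to the given height."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = [f"{prefix}{i + 1:02d}" for i in range(n_tips)]
    nwk = _yule_newick(labels, rng, height) + ";"
    return _phylogeny_from_newick_string(nwk)


def simulate_split_clade(split: tuple[int, int], rng: np.random.Generator,
                         prefix: str = "sp") -> Phylogeny:
    """Unit-height tree with two monophyletic sister subclades of given sizes."""
    n1, n2 = split
    labels = [f"{prefix}{i + 1:02d}" for i in range(n1 + n2)]
    sub_height = 0.5

    def subclade(lbls: list[str]) -> str:
        if len(lbls) == 1:  # single-tip subclade: the stem is the whole root-to-tip path
            return f"{lbls[0]}:1"
        return f"{_yule_newick(lbls, rng, sub_height)}:{1.0 - sub_height:.10g}"

    nwk = f"({subclade(labels[:n1])},{subclade(labels[n1:])});"
    return _phylogeny_from_newick_string(nwk)


def bm_simulate(
    tree: Phylogeny,
    rate,
    seed: int | np.random.Generator = 0,
    root_value=0.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate Brownian-motion traits along the tree.

    ``rate`` is either a scalar variance per unit branch length (one
    trait) or a positive-definite k x k rate matrix (k correlated
    traits).  Tip values are multivariate normal with covariance
    kron(rate, C).  Returns a DataFrame indexed by tip label.
    """
    if rng is None:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    R = np.atleast_2d(np.asarray(rate, dtype=float))
    k = R.shape[0]
    try:
        LR = np.linalg.cholesky(R)
    except np.linalg.LinAlgError as exc:
        raise ValueError("rate matrix must be positive definite") from exc
    root = np.broadcast_to(np.asarray(root_value, dtype=float), (k,)).copy()

    values: dict[int, np.ndarray] = {}
    out: dict[str, np.ndarray] = {}
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            values[id(node)] = root
        else:
            el = float(node.edge.length or 0.0)
            step = LR @ rng.standard_normal(k) * math.sqrt(el) if el > 0 else np.zeros(k)
            values[id(node)] = values[id(node.parent_node)] + step
        if node.is_leaf():
            out[node.taxon.label] = values[id(node)]
    df = pd.DataFrame.from_dict(out, orient="index")
    df = df.loc[tree.tip_labels]
    df.columns = [f"trait_{i}" for i in range(k)]
    return df


# ---------------------------------------------------------------------------
# rank statistics


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    method: str  # 'exact-permutation' or 't-approximation'


def spearman(x, y, exact_max_n: int = 10) -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties.

    The two-sided p-value is computed by full permutation enumeration for
    n <= ``exact_max_n`` and by the t approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    n = len(x)
    rho, p_t = st.spearmanr(x, y)
    rho = float(rho)
    if n > exact_max_n:
        return CorrelationResult(rho, float(p_t), n, "t-approximation")

    rx = st.rankdata(x) - (n + 1) / 2.0
    ry = st.rankdata(y) - (n + 1) / 2.0
    # |rho| order statistics reduce to |dot| since the permuted vector's norm
    # is permutation invariant
    obs = abs(float(rx @ ry))
    tol = 1e-9 * max(obs, 1.0)
    count = 0
    total = math.factorial(n)
    it = itertools.permutations(ry)
    chunk = 200_000
    while True:
        block = list(itertools.islice(it, chunk))
        if not block:
            break
        dots = np.abs(np.asarray(block) @ rx)
        count += int(np.sum(dots >= obs - tol))
    return CorrelationResult(rho, count / total, n, "exact-permutation")


def wilcoxon_signed_rank(x, y=None, exact_max_n: int = 25) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired data.

    Zero differences are dropped.  The null distribution is enumerated
    exactly (handling tied average ranks) for n <= ``exact_max_n``; larger
    samples use the normal approximation with continuity and tie
    corrections.
    """
    d = np.asarray(x, dtype=float) - (0.0 if y is None else np.asarray(y, dtype=float))
    d = d[d != 0]
    n = len(d)
    if n < 3:
        raise ValueError("need at least 3 nonzero differences")
    ranks = st.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())

    if n <= exact_max_n:
        # exact null: distribution of W+ over all 2^n sign assignments,
        # via subset-sum counting on doubled (integer) ranks
        r2 = np.rint(2 * ranks).astype(np.int64)
        total = int(r2.sum())
        counts = np.zeros(total + 1, dtype=float)
        counts[0] = 1.0
        for r in r2:
            counts[r:] += counts[: total + 1 - r].copy()
        counts /= counts.sum()
        w2 = int(round(2 * w_pos))
        lo = counts[: w2 + 1].sum()
        hi = counts[w2:].sum()
        return float(min(1.0, 2.0 * min(lo, hi)))

    mu = n * (n + 1) / 4.0
    tie_term = 0.0
    _, t_counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(t_counts**3 - t_counts)) / 48.0
    sd = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
    z = (w_pos - mu - 0.5 * np.sign(w_pos - mu)) / sd
    return float(2.0 * st.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# PGLS under Pagel's lambda


@dataclass(frozen=True)
class PGLSResult:
    slope: float
    intercept: float
    lambda_: float
    lambda_mode: str
    p_value: float
    adjusted_R2: float
    log_likelihood: float
    n: int
    lambda_bounds: dict[str, float] | None = None  # LR p-values vs lambda = 0 and 1


def _lambda_cov(C: np.ndarray, lam: float) -> np.ndarray:
    V = lam * C
    np.fill_diagonal(V, np.diag(C))
    return V


def _gls(y: np.ndarray, X: np.ndarray, V: np.ndarray):
    """GLS fit; returns (beta, rss, logdetV, XtViX_inv, cho)."""
    try:
        cho = cho_factor(V, lower=True)
    except np.linalg.LinAlgError as exc:
        raise ValueError("phylogenetic covariance matrix is singular") from exc
    ViX = cho_solve(cho, X)
    Viy = cho_solve(cho, y)
    XtViX = X.T @ ViX
    beta = np.linalg.solve(XtViX, X.T @ Viy)
    resid = y - X @ beta
    rss = float(resid @ cho_solve(cho, resid))
    logdet = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    return beta, rss, logdet, np.linalg.inv(XtViX)


def _profile_ll(y: np.ndarray, X: np.ndarray, C: np.ndarray, lam: float) -> float:
    n = len(y)
    _, rss, logdet, _ = _gls(y, X, _lambda_cov(C, lam))
    sigma2 = rss / n
    if not np.isfinite(sigma2) or sigma2 <= 0:
        raise ValueError("non-finite likelihood in PGLS")
    return -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet + n)


def _ml_lambda(y: np.ndarray, X: np.ndarray, C: np.ndarray) -> tuple[float, float]:
    grid = np.linspace(0.0, 1.0, 101)
    lls = np.array([_profile_ll(y, X, C, g) for g in grid])
    i = int(np.argmax(lls))
    lo, hi = max(0.0, grid[i] - 0.02), min(1.0, grid[i] + 0.02)
    best_lam, best_ll = float(grid[i]), float(lls[i])
    try:
        res = minimize_scalar(lambda g: -_profile_ll(y, X, C, g), bounds=(lo, hi), method="bounded")
        if res.success and -res.fun > best_ll:
            best_lam, best_ll = float(res.x), float(-res.fun)
    except ValueError:
        pass
    return best_lam, best_ll


def pgls(y, x, tree: Phylogeny, lambda_mode: str = "ml") -> PGLSResult:
    """Simple PGLS regression of y on x under Pagel's lambda covariance.

    ``lambda_mode`` is 'ml' (profile maximum likelihood over [0, 1]),
    'fixed0' (ordinary least squares) or 'fixed1' (Brownian motion).
    In ML mode, likelihood-ratio tests of the lambda bounds are reported
    with a chi-squared(1) reference halved at the boundary; a test of the
    bound that the estimate itself hits returns p = 1.
    """
    yv = tree.align(y)
    xv = tree.align(x)
    n = tree.n_tips
    if n < 4:
        raise ValueError("PGLS needs more tips than coefficients + 1")
    C = tree.cov_matrix()
    X = np.column_stack([np.ones(n), xv])

    bounds = None
    if lambda_mode == "ml":
        lam, ll = _ml_lambda(yv, X, C)
        ll0 = _profile_ll(yv, X, C, 0.0)
        ll1 = _profile_ll(yv, X, C, 1.0)
        p0 = 1.0 if lam <= 1e-8 else float(min(1.0, 0.5 * st.chi2.sf(2 * (ll - ll0), 1)))
        p1 = 1.0 if lam >= 1 - 1e-8 else float(min(1.0, 0.5 * st.chi2.sf(2 * (ll - ll1), 1)))
        bounds = {"lambda0": p0, "lambda1": p1}
    elif lambda_mode == "fixed0":
        lam = 0.0
        ll = _profile_ll(yv, X, C, lam)
    elif lambda_mode == "fixed1":
        lam = 1.0
        ll = _profile_ll(yv, X, C, lam)
    else:
        raise ValueError(f"unknown lambda_mode {lambda_mode!r}")

    V = _lambda_cov(C, lam)
    beta, rss, _, XtViX_inv = _gls(yv, X, V)
    sigma2 = rss / (n - 2)
    se = math.sqrt(sigma2 * XtViX_inv[1, 1])
    t = beta[1] / se if se > 0 else np.inf
    p = float(2 * st.t.sf(abs(t), n - 2))
    # R^2 against the GLS intercept-only model at the same lambda
    _, rss0, _, _ = _gls(yv, np.ones((n, 1)), V)
    r2 = 1.0 - rss / rss0
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return PGLSResult(
        slope=float(beta[1]),
        intercept=float(beta[0]),
        lambda_=float(lam),
        lambda_mode=lambda_mode,
        p_value=p,
        adjusted_R2=float(adj),
        log_likelihood=float(ll),
        n=n,
        lambda_bounds=bounds,
    )


@dataclass(frozen=True)
class PairedTTestResult:
    t: float
    df: float
    p_value: float
    lambda_: float
    mean_diff: float


def phyl_paired_ttest(y1, y2, tree: Phylogeny) -> PairedTTestResult:
    """Phylogenetic paired t-test.

    The paired differences d = y1 - y2 are modelled as a single trait with
    mean mu and Pagel's-lambda covariance sigma^2 C(lambda).  lambda and
    sigma^2 are estimated by restricted maximum likelihood (REML) on d,
    and mu is tested against zero with a t statistic.  Because lambda is
    itself estimated, the naive GLS standard error of mu is too small in
    small samples; the variance receives a Kackar-Harville correction and
    the reference distribution uses Satterthwaite degrees of freedom
    (capped at n - 1).  On a star tree the covariance parameters drop out
    and the test reduces exactly to the ordinary paired t-test.
    """
    d = tree.align(y1) - tree.align(y2)
    n = tree.n_tips
    if np.ptp(d) <= 1e-12 * max(1.0, float(np.max(np.abs(d)))):
        raise ValueError("paired differences have (near-)zero variance")
    C = tree.cov_matrix()
    one = np.ones(n)
    diagC = np.diag(C).copy()
    Coff = C - np.diag(diagC)

    def reml_ll(s2: float, lam: float) -> float:
        V = s2 * (lam * Coff + np.diag(diagC))
        cho = cho_factor(V, lower=True)
        Vi1 = cho_solve(cho, one)
        den = float(one @ Vi1)
        mu = float(d @ Vi1) / den
        r = d - mu
        rss = float(r @ cho_solve(cho, r))
        logdet = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
        return -0.5 * (rss + logdet + math.log(den) + (n - 1) * math.log(2 * math.pi))

    def profile(lam: float) -> tuple[float, float]:
        V1 = lam * Coff + np.diag(diagC)
        cho = cho_factor(V1, lower=True)
        Vi1 = cho_solve(cho, one)
        den = float(one @ Vi1)
        mu = float(d @ Vi1) / den
        r = d - mu
        s2 = float(r @ cho_solve(cho, r)) / (n - 1)
        return s2, reml_ll(s2, lam)

    grid = np.linspace(0.0, 1.0, 41)
    prof = [profile(g) for g in grid]
    i = int(np.argmax([p[1] for p in prof]))
    lam, s2 = float(grid[i]), prof[i][0]

    V = s2 * (lam * Coff + np.diag(diagC))
    Vi = np.linalg.inv(V)
    Vi1 = Vi @ one
    m = float(one @ Vi1)
    mu = float(d @ Vi1) / m
    P = Vi - np.outer(Vi1, Vi1) / m

    # observed REML information over (log sigma^2, lambda); the Hessian is
    # evaluated without clamping lambda so boundary estimates still carry
    # curvature (C(lambda) stays PD slightly outside [0, 1])
    def ll_vec(p: np.ndarray) -> float:
        try:
            return reml_ll(math.exp(p[0]), p[1])
        except np.linalg.LinAlgError:
            return -np.inf

    p0 = np.array([math.log(s2), lam])
    h = np.array([1e-3, 1e-3])
    H = np.zeros((2, 2))
    finite = True
    for a in range(2):
        for b in range(2):
            pa, pb = np.eye(2)[a] * h[a], np.eye(2)[b] * h[b]
            vals = [ll_vec(p0 + pa + pb), ll_vec(p0 + pa - pb),
                    ll_vec(p0 - pa + pb), ll_vec(p0 - pa - pb)]
            if not np.all(np.isfinite(vals)):
                finite = False
                break
            H[a, b] = (vals[0] - vals[1] - vals[2] + vals[3]) / (4 * h[a] * h[b])
    W = np.zeros((2, 2))
    if finite:
        try:
            Wc = np.linalg.inv(-H)
            if np.all(np.isfinite(Wc)) and Wc[0, 0] >= 0 and Wc[1, 1] >= 0:
                W = Wc
        except np.linalg.LinAlgError:
            pass  # flat direction (e.g. star tree): no correction needed

    a1 = V @ Vi1  # dV/d(log s2) @ Vi1
    a2 = (s2 * Coff) @ Vi1  # dV/dlambda @ Vi1
    B = np.array([[a1 @ P @ a1, a1 @ P @ a2], [a1 @ P @ a2, a2 @ P @ a2]])
    var_adj = 1.0 / m + float(W[0, 0] * B[0, 0] + 2 * W[0, 1] * B[0, 1] + W[1, 1] * B[1, 1]) / m**2

    def var_mu(p: np.ndarray) -> float:
        V_ = math.exp(p[0]) * (p[1] * Coff + np.diag(diagC))
        return 1.0 / float(one @ np.linalg.solve(V_, one))

    try:
        gr = np.array(
            [(var_mu(p0 + np.eye(2)[a] * h[a]) - var_mu(p0 - np.eye(2)[a] * h[a])) / (2 * h[a])
             for a in range(2)]
        )
        var_g = float(gr @ W @ gr)
    except np.linalg.LinAlgError:
        var_g = 0.0
    df = float(n - 1) if var_g <= 0 else min(float(n - 1), 2 * var_adj**2 / var_g)
    df = max(df, 2.0)
    t = mu / math.sqrt(var_adj)
    p = float(2 * st.t.sf(abs(t), df))
    return PairedTTestResult(t=float(t), df=df, p_value=p, lambda_=lam, mean_diff=mu)


# ---------------------------------------------------------------------------
# the correlation suite


REQUIRED_COLUMNS = (
    "peak_vm_impact",
    "peak_vm_torsion",
    "sigma_cr",
    "tau_max",
    "width",
    "depth",
    "body_length",
)

#: (predictor, response) model pairs reported by the comparative analysis
SUITE_PAIRS = (
    ("peak_vm_torsion", "peak_vm_impact"),
    ("sigma_cr", "peak_vm_impact"),
    ("tau_max", "peak_vm_torsion"),
    ("body_length", "peak_vm_impact"),
    ("body_length", "peak_vm_torsion"),
)


def validate_comparative_table(table: pd.DataFrame, tree: Phylogeny) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"comparative table is missing columns: {missing}")
    if set(table.index) != set(tree.tip_labels):
        raise ValueError("comparative table row labels do not match tree tips")
    perf = table[["peak_vm_impact", "peak_vm_torsion", "sigma_cr", "tau_max"]]
    if (perf <= 0).any().any():
        raise ValueError("performance values must be positive")
    return table.loc[tree.tip_labels]


def run_correlation_suite(table: pd.DataFrame, tree: Phylogeny) -> pd.DataFrame:
    """Spearman + PGLS (lambda in {ML, 0, 1}) for each predictor/response pair.

    Returns a long table with one row per model per lambda treatment
    (5 pairs x 3 treatments).
    """
    tab = validate_comparative_table(table, tree)
    rows = []
    for pred, resp in SUITE_PAIRS:
        x, y = tab[pred], tab[resp]
        corr = spearman(x.to_numpy(), y.to_numpy())
        for mode in ("ml", "fixed0", "fixed1"):
            fit = pgls(y, x, tree, lambda_mode=mode)
            rows.append(
                {
                    "predictor": pred,
                    "response": resp,
                    "spearman_rho": corr.rho,
                    "spearman_p": corr.p_value,
                    "lambda_mode": mode,
                    "lambda": fit.lambda_,
                    "slope": fit.slope,
                    "intercept": fit.intercept,
                    "p_value": fit.p_value,
                    "adjusted_R2": fit.adjusted_R2,
                    "lambda0_p": (fit.lambda_bounds or {}).get("lambda0", np.nan),
                    "lambda1_p": (fit.lambda_bounds or {}).get("lambda1", np.nan),
                    "log_likelihood": fit.log_likelihood,
                }
            )
    return pd.DataFrame(rows)
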