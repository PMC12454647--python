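"""Two-binary-trait gain/loss model on a species tree.

Two gene families A and B are modelled as a continuous-time Markov chain on
the joint state space (00, 01, 10, 11), where the first bit is A and the
second is B.  Each trait has a gain and a loss rate per unit branch length;
in the *dependent* model the presence of the partner trait multiplies the
other trait's gain rate by g and its loss rate by l (four multipliers in
total, so 8 free parameters against 4 for the *independent* model where all
multipliers are fixed at 1).  Simultaneous double transitions (00↔11,
01↔10) have rate zero.

"Complementary" phylogenetic distributions (families that avoid each other,
as functionally redundant genes do) correspond to gain multipliers < 1 and
loss multipliers > 1; "correlated" distributions (functionally coupled
genes) to the reverse.  The interaction is tested by a likelihood-ratio
test of the dependent against the nested independent model with 4 degrees
of freedom; the multipliers are interior parameters so the chi-square
reference applies without boundary corrections.

Likelihoods are computed by Felsenstein pruning with per-branch transition
matrices expm(Q t), evaluated for all branches at once through the
eigendecomposition of Q (with a scaling-and-squaring fallback for
ill-conditioned eigenvector matrices).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import dendropy
import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize
from scipy.stats import chi2

from .records import PresenceAbsenceMatrix

STATES = ("00", "01", "10", "11")
STATE_INDEX = {s: i for i, s in enumerate(STATES)}

#: Bounds for all rates and multipliers during optimization.
PARAM_LOWER = 1e-4
PARAM_UPPER = 1e4


@dataclass
class PairRateModel:
    """Gain/loss rates for two traits plus interaction multipliers.

    ``g_a`` multiplies A's gain rate when B is present; ``l_a`` multiplies
    A's loss rate when B is present (symmetrically for B).  All parameters
    must be positive; multipliers equal to 1 recover the independent model.
    """

    gain_a: float = 1.0
    loss_a: float = 1.0
    gain_b: float = 1.0
    loss_b: float = 1.0
    g_a: float = 1.0
    l_a: float = 1.0
    g_b: float = 1.0
    l_b: float = 1.0

    def __post_init__(self) -> None:
        for name in ("gain_a", "loss_a", "gain_b", "loss_b"):
            v = getattr(self, name)
            if not (v > 0):
                raise ValueError(f"{name} must be > 0, got {v}")
        # multipliers of exactly 0 are allowed (an absolute veto of a
        # transition, useful in simulation); fitting keeps them positive
        for name in ("g_a", "l_a", "g_b", "l_b"):
            v = getattr(self, name)
            if not (v >= 0):
                raise ValueError(f"{name} must be >= 0, got {v}")

    def as_array(self, kind: str = "dependent") -> np.ndarray:
        base = [self.gain_a, self.loss_a, self.gain_b, self.loss_b]
        if kind == "independent":
            return np.array(base)
        return np.array(base + [self.g_a, self.l_a, self.g_b, self.l_b])

    @classmethod
    def from_array(cls, x: np.ndarray) -> "PairRateModel":
        x = np.asarray(x, dtype=float)
        if x.size == 4:
            return cls(*x)
        return cls(*x[:8])


def build_rate_matrix(model: PairRateModel) -> np.ndarray:
    """4×4 generator over states (00, 01, 10, 11); rows sum to zero.

    For example rate(00→10) = gain_a, rate(01→11) = gain_a·g_a (B present),
    rate(11→10) = loss_b·l_b (A present).  Double-flip entries are 0.
    """
    Q = np.zeros((4, 4))
    Q[STATE_INDEX["00"], STATE_INDEX["10"]] = model.gain_a
    Q[STATE_INDEX["00"], STATE_INDEX["01"]] = model.gain_b
    Q[STATE_INDEX["01"], STATE_INDEX["11"]] = model.gain_a * model.g_a
    Q[STATE_INDEX["01"], STATE_INDEX["00"]] = model.loss_b
    Q[STATE_INDEX["10"], STATE_INDEX["11"]] = model.gain_b * model.g_b
    Q[STATE_INDEX["10"], STATE_INDEX["00"]] = model.loss_a
    Q[STATE_INDEX["11"], STATE_INDEX["01"]] = model.loss_a * model.l_a
    Q[STATE_INDEX["11"], STATE_INDEX["10"]] = model.loss_b * model.l_b
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """Stationary distribution of the generator; uniform fallback if it is
    not uniquely defined (reducible chain)."""
    A = Q.T.copy()
    A[3, :] = 1.0  # replace one redundant balance equation with normalization
    b = np.array([0.0, 0.0, 0.0, 1.0])
    try:
        pi = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return np.full(4, 0.25)
    if (pi < -1e-9).any() or not np.isfinite(pi).all():
        return np.full(4, 0.25)
    pi = np.clip(pi, 0.0, None)
    s = pi.sum()
    if s <= 0 or np.abs(Q.T @ pi).max() > 1e-6 * max(1.0, np.abs(Q).max()):
        return np.full(4, 0.25)
    return pi / s


# ---------------------------------------------------------------------------
# Tree indexing for fast repeated pruning


class TreeIndex:
    """Flattened postorder view of a tree for vectorized pruning.

    Nodes are numbered 0..N-1 with tips first; internal nodes are grouped
    into levels such that all children of a level are computed before the
    level itself, allowing the per-level combine step to be vectorized.
    """

    def __init__(self, tree: dendropy.Tree):
        tips = list(tree.leaf_node_iter())
        internals = [n for n in tree.postorder_node_iter() if not n.is_leaf()]
        self.tip_labels = [t.taxon.label for t in tips]
        self.n_tips = len(tips)
        self.n_nodes = len(tips) + len(internals)
        index = {id(n): i for i, n in enumerate(tips)}
        for j, n in enumerate(internals):
            index[id(n)] = self.n_tips + j
        # edge length above each node (root edge length irrelevant: 0)
        lengths = np.zeros(self.n_nodes)
        for n in list(tips) + internals:
            lengths[index[id(n)]] = n.edge.length or 0.0
        self.edge_lengths = lengths
        self.root_index = index[id(tree.seed_node)]

        # group internal nodes into levels by max child depth
        depth: dict[int, int] = {}
        for n in tips:
            depth[id(n)] = 0
        levels: dict[int, list[dendropy.Node]] = {}
        for n in internals:
            d = 1 + max(depth[id(c)] for c in n.child_nodes())
            depth[id(n)] = d
            levels.setdefault(d, []).append(n)
        self.levels: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
        for d in sorted(levels):
            nodes = levels[d]
            child_idx = []
            seg_starts = []
            parent_idx = []
            pos = 0
            for n in nodes:
                kids = n.child_nodes()
                seg_starts.append(pos)
                for c in kids:
                    child_idx.append(index[id(c)])
                pos += len(kids)
                parent_idx.append(index[id(n)])
            self.levels.append(
                (
                    np.array(parent_idx, dtype=np.intp),
                    np.array(child_idx, dtype=np.intp),
                    np.array(seg_starts, dtype=np.intp),
                )
            )


def _transition_matrices(Q: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """expm(Q t) for every branch length, vectorized via eigendecomposition."""
    w, V = np.linalg.eig(Q)
    use_eig = True
    try:
        Vinv = np.linalg.inv(V)
        # cheap condition estimate; SVD-exact cond is not worth the cost here
        if np.abs(V).sum() * np.abs(Vinv).sum() > 1e8:
            use_eig = False
    except np.linalg.LinAlgError:
        use_eig = False
    if use_eig:
        E = np.exp(np.outer(lengths, w))  # (n_edges, 4)
        P = np.einsum("ij,ej,jk->eik", V, E, Vinv).real
    else:
        # scaling-and-squaring per unique branch length, cached
        uniq, inverse = np.unique(lengths, return_inverse=True)
        mats = np.stack([expm(Q * t) for t in uniq])
        P = mats[inverse]
    P = np.clip(P, 0.0, None)
    # renormalize away roundoff; rows of expm(Qt) sum to exactly 1
    P /= P.sum(axis=2, keepdims=True)
    return P


def _resolve_tip_states(
    index: TreeIndex, tip_states: Union[dict, PresenceAbsenceMatrix]
) -> np.ndarray:
    if isinstance(tip_states, PresenceAbsenceMatrix):
        if len(tip_states.families) != 2:
            raise ValueError("presence matrix must be restricted to two families")
        df = tip_states.df
        states = {
            sp: f"{int(df.iloc[i, 0])}{int(df.iloc[i, 1])}"
            for i, sp in enumerate(df.index)
        }
    else:
        states = dict(tip_states)
    out = np.empty(index.n_tips, dtype=np.intp)
    for i, label in enumerate(index.tip_labels):
        if label not in states:
            raise ValueError(f"tip {label!r} has no state")
        s = states[label]
        out[i] = STATE_INDEX[s] if isinstance(s, str) else int(s)
    return out


def prune_likelihood(
    tree: Union[dendropy.Tree, TreeIndex],
    tip_states: Union[dict, PresenceAbsenceMatrix],
    Q: np.ndarray,
    root_prior: Union[str, np.ndarray] = "stationary",
) -> float:
    """Log-likelihood of joint tip states under the 4-state chain.

    ``tip_states`` maps tip label → state ("00".."11" or index 0..3), or is a
    two-family presence matrix whose rows match the tree tips.  ``root_prior``
    is "stationary" (of Q), "uniform", or an explicit length-4 vector.
    """
    index = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    states = _resolve_tip_states(index, tip_states)
    if isinstance(root_prior, str):
        if root_prior == "stationary":
            prior = stationary_distribution(Q)
        elif root_prior == "uniform":
            prior = np.full(4, 0.25)
        else:
            raise ValueError(f"unknown root prior {root_prior!r}")
    else:
        prior = np.asarray(root_prior, dtype=float)

    tip_partial = np.zeros((index.n_tips, 4))
    tip_partial[np.arange(index.n_tips), states] = 1.0
    return _prune_core(index, tip_partial, Q, prior)


def _prune_core(
    index: TreeIndex, tip_partial: np.ndarray, Q: np.ndarray, prior: np.ndarray
) -> float:
    """Pruning over the flattened tree given precomputed tip partials."""
    P = _transition_matrices(Q, index.edge_lengths)
    partial = np.empty((index.n_nodes, 4))
    partial[: index.n_tips] = tip_partial
    log_scale = 0.0
    for parent_idx, child_idx, seg_starts in index.levels:
        # conditional likelihood flowing up each child's edge
        M = np.einsum("eij,ej->ei", P[child_idx], partial[child_idx])
        prod = np.multiply.reduceat(M, seg_starts, axis=0)
        scale = prod.max(axis=1)
        scale[scale == 0] = 1.0
        partial[parent_idx] = prod / scale[:, None]
        log_scale += np.log(scale).sum()
    lik = float(prior @ partial[index.root_index])
    if lik <= 0:
        return -np.inf
    return float(np.log(lik) + log_scale)


# ---------------------------------------------------------------------------
# Fitting


@dataclass
class FitResult:
    kind: str
    model: PairRateModel
    log_likelihood: float
    converged: bool
    n_restarts: int
    warnings: list[str] = field(default_factory=list)
    data_key: Optional[int] = None

    @property
    def n_parameters(self) -> int:
        return 4 if self.kind == "independent" else 8


def _data_fingerprint(index: TreeIndex, states: np.ndarray) -> int:
    return hash((tuple(index.tip_labels), tuple(int(s) for s in states)))


def fit_model(
    tree: Union[dendropy.Tree, TreeIndex],
    matrix: Union[PresenceAbsenceMatrix, dict],
    kind: str = "dependent",
    n_restarts: int = 5,
    seed: int = 0,
    root_prior: str = "stationary",
    maxiter: int = 300,
    init: Optional[PairRateModel] = None,
) -> FitResult:
    """Maximum-likelihood fit of the dependent or independent pair model.

    Optimization runs in log-parameter space (bounds [1e-4, 1e4]) with
    L-BFGS-B and up to ``n_restarts`` seeded starts; restarts stop early
    once two of them agree within 0.01 logL units, and the convergence flag
    is False when no two restarts agree that closely (a rugged or flat
    surface).  A trait that is constant across tips leaves its rates weakly
    identified; this is flagged as a warning, not an error.

    The dependent model's likelihood surface has flat ridges: with binary
    tip data, suppressed gain (g ≪ 1) and accelerated loss (l ≫ 1) of a
    trait can be nearly observationally equivalent, and the two traits'
    multipliers trade off against each other, so the raw optimizer endpoint
    is an arbitrary point of a near-degenerate set and its quadrant is not
    interpretable.  The fit therefore proceeds in stages: a trait-symmetric
    stage (g_a = g_b, l_a = l_b; 6 free parameters, multistart), an
    unconstrained 8-parameter polish (whose likelihood is the one reported
    and used in the LRT), and two quadrant-profile refits constrained to
    the complementary (g ≤ 1 ≤ l) and correlated (l ≤ 1 ≤ g) quadrants.
    When one quadrant beats the other by more than 2 logL units, its
    constrained optimum — a representative of the near-optimal set with an
    interpretable sign — is reported as the fitted model; otherwise the
    interaction direction is not resolved and the unconstrained point is
    reported as-is.
    """
    if kind not in ("dependent", "independent"):
        raise ValueError(f"kind must be dependent|independent, got {kind!r}")
    index = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    states = _resolve_tip_states(index, matrix)
    warns: list[str] = []
    a_bits = (states >= 2).astype(int)
    b_bits = (states % 2).astype(int)
    for name, bits in (("A", a_bits), ("B", b_bits)):
        if bits.min() == bits.max():
            warns.append(
                f"trait {name} is constant across tips; its rates are weakly identified"
            )

    n_free = 4 if kind == "independent" else 8
    # initial rate guess: one expected event per root-to-tip path
    depth = float(np.mean(index.edge_lengths)) * np.log2(max(index.n_tips, 2))
    rate0 = 1.0 / max(depth, 1e-3)

    lo, hi = np.log(PARAM_LOWER), np.log(PARAM_UPPER)
    tip_partial = np.zeros((index.n_tips, 4))
    tip_partial[np.arange(index.n_tips), states] = 1.0
    if root_prior == "uniform":
        fixed_prior: Optional[np.ndarray] = np.full(4, 0.25)
    elif root_prior == "stationary":
        fixed_prior = None  # recomputed from each candidate Q
    else:
        raise ValueError(f"unknown root prior {root_prior!r}")

    def make_objective(expand):
        def objective(x: np.ndarray) -> float:
            model = PairRateModel(*expand(np.exp(x)))
            Q = build_rate_matrix(model)
            prior = stationary_distribution(Q) if fixed_prior is None else fixed_prior
            ll = _prune_core(index, tip_partial, Q, prior)
            return -ll if np.isfinite(ll) else 1e12
        return objective

    def multistart(objective, x0_base, n_params, rng, budget):
        # adaptive: restarts run until two of them agree within 0.01 logL
        # units of the running best (or the budget is exhausted)
        results = []
        for r in range(max(1, budget)):
            x0 = x0_base if r == 0 else np.clip(
                x0_base + rng.normal(scale=1.0, size=n_params), lo, hi
            )
            res = minimize(
                objective,
                x0,
                method="L-BFGS-B",
                bounds=[(lo, hi)] * n_params,
                options={"maxiter": maxiter, "ftol": 1e-10},
            )
            results.append(res)
            if len(results) >= 2:
                lls = np.sort([-q.fun for q in results])
                if lls[-2] >= lls[-1] - 0.01:
                    break
        lls = np.array([-q.fun for q in results])
        best = int(np.argmax(lls))
        agreed = len(results) == 1 or (np.sort(lls)[-2] >= lls[best] - 0.01)
        return results[best].x, float(lls[best]), agreed

    rng = np.random.default_rng(seed)
    base_rates = (
        np.clip(np.log(init.as_array("independent")), lo, hi)
        if init is not None
        else np.log(np.full(4, rate0))
    )

    if kind == "independent":
        x, ll, agreed = multistart(
            make_objective(lambda th: th), base_rates, 4, rng, n_restarts
        )
        model = PairRateModel(*np.exp(x))
    else:
        # stage 1: trait-symmetric multipliers (g, l shared by both traits)
        if init is not None:
            sym0 = np.concatenate(
                [
                    np.clip(np.log(init.as_array("dependent")[:4]), lo, hi),
                    np.clip(
                        np.log([np.sqrt(init.g_a * init.g_b), np.sqrt(init.l_a * init.l_b)]),
                        lo,
                        hi,
                    ),
                ]
            )
        else:
            sym0 = np.concatenate([base_rates, np.zeros(2)])
        expand_sym = lambda th: (th[0], th[1], th[2], th[3], th[4], th[5], th[4], th[5])
        x_sym, ll_sym, agreed = multistart(
            make_objective(expand_sym), sym0, 6, rng, n_restarts
        )
        th_sym = np.exp(x_sym)
        x_full0 = np.log(np.array(expand_sym(th_sym)))

        def polish(bounds, x0):
            x0 = np.array([min(max(v, b[0]), b[1]) for v, b in zip(x0, bounds)])
            res = minimize(
                make_objective(lambda th: th),
                x0,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": maxiter, "ftol": 1e-10},
            )
            return -float(res.fun), np.exp(res.x)

        # stage 2: unconstrained polish -> the likelihood used in the LRT
        ll_full, th_full = polish([(lo, hi)] * 8, x_full0)
        ll = max(ll_full, ll_sym)

        # stage 3: quadrant-profile refits deciding the interaction direction
        eps = 1e-6  # keeps quadrant representatives strictly off multiplier 1
        g_down, l_up = (lo, -eps), (eps, hi)
        g_up, l_down = (eps, hi), (lo, -eps)
        comp_bounds = [(lo, hi)] * 4 + [g_down, l_up, g_down, l_up]
        corr_bounds = [(lo, hi)] * 4 + [g_up, l_down, g_up, l_down]
        ll_comp, th_comp = polish(comp_bounds, x_full0)
        ll_corr, th_corr = polish(corr_bounds, x_full0)
        margin = 2.0
        if ll_comp > ll_corr + margin:
            model = PairRateModel(*th_comp)
            ll = max(ll, ll_comp)
        elif ll_corr > ll_comp + margin:
            model = PairRateModel(*th_corr)
            ll = max(ll, ll_corr)
        elif ll_full >= ll_sym + 0.01:
            model = PairRateModel(*th_full)
        else:
            model = PairRateModel(*expand_sym(th_sym))
    return FitResult(
        kind=kind,
        model=model,
        log_likelihood=ll,
        converged=bool(agreed),
        n_restarts=max(1, n_restarts),
        warnings=warns,
        data_key=_data_fingerprint(index, states),
    )


@dataclass
class LRTResult:
    statistic: float
    df: int
    p_value: float


def lrt_interaction(fit_dep: FitResult, fit_indep: FitResult) -> LRTResult:
    """Likelihood-ratio test for the four interaction multipliers (df = 4).

    The statistic 2·(logL_dep − logL_indep) is floored at 0 (nesting can be
    violated by a hair of optimizer tolerance).
    """
    if fit_dep.kind != "dependent" or fit_indep.kind != "independent":
        raise ValueError("pass (dependent fit, independent fit) in that order")
    if fit_dep.data_key != fit_indep.data_key:
        raise ValueError("fits were computed on different data")
    if not (fit_dep.converged and fit_indep.converged):
        warnings.warn("LRT computed from fits flagged as not converged")
    stat = max(0.0, 2.0 * (fit_dep.log_likelihood - fit_indep.log_likelihood))
    return LRTResult(statistic=stat, df=4, p_value=float(chi2.sf(stat, 4)))


@dataclass
class InteractionTest:
    fit_independent: FitResult
    fit_dependent: FitResult
    lrt: LRTResult
    sign: str


def test_interaction(
    tree: Union[dendropy.Tree, TreeIndex],
    matrix: Union[PresenceAbsenceMatrix, dict],
    n_restarts: int = 5,
    seed: int = 0,
    root_prior: str = "stationary",
) -> InteractionTest:
    """Fit both models, run the LRT and classify the interaction sign.

    The dependent fit warm-starts from the independent estimates (with
    multipliers at 1); its restarts perturb around that point.  Because the
    independent optimum lies inside the dependent parameter space, this
    start guarantees logL_dep ≥ logL_indep up to optimizer tolerance.
    """
    index = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    fit_i = fit_model(
        index, matrix, "independent",
        n_restarts=n_restarts, seed=seed, root_prior=root_prior,
    )
    fit_d = fit_model(
        index, matrix, "dependent",
        n_restarts=n_restarts, seed=seed + 1, root_prior=root_prior,
        init=fit_i.model,
    )
    lrt = lrt_interaction(fit_d, fit_i)
    return InteractionTest(
        fit_independent=fit_i,
        fit_dependent=fit_d,
        lrt=lrt,
        sign=interaction_sign(fit_d),
    )


def interaction_sign(fit_dep: FitResult) -> str:
    """Classify the fitted interaction: complementary, correlated, or none.

    Complementary: partner presence suppresses gain (geometric-mean g < 1)
    and accelerates loss (geometric-mean l > 1).  Correlated is the reverse;
    anything mixed is "none".
    """
    m = fit_dep.model
    g = float(np.sqrt(m.g_a * m.g_b))
    l = float(np.sqrt(m.l_a * m.l_b))
    if g < 1.0 and l > 1.0:
        return "complementary"
    if g > 1.0 and l < 1.0:
        return "correlated"
    return "none"
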