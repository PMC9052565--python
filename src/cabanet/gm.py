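"""Graphical-Markov network estimation with bootstrap stability selection.

The estimator is a PC-style skeleton search over partial-correlation
conditional-independence tests (Fisher-z), wrapped in a nonparametric
patient-level bootstrap: an unordered variable pair is reported as associated
when its edge survives the skeleton search in more than half of the bootstrap
iterations at the chosen alpha (the ">500 of 1000" rule), and the sign of the
association is the sign of the last surviving partial correlation, voted
across iterations.

Tests that cannot be computed (singular correlation submatrices, zero
variance, insufficient sample) return an *incomputable* signal rather than
raising, and the skeleton search skips them with the edge retained for that
conditioning set — the estimation must never abort mid-run.  Near-singular
but non-degenerate submatrices are stabilized with a small ridge on the
correlation matrix diagonal.

Performance notes: the skeleton runs thousands of times inside the bootstrap,
so all level-0 tests come from one correlation matrix, level-1 tests use the
closed-form single-variable recursion evaluated vectorized over candidate
conditioning sets, and higher levels use stacked submatrix inversions; only
degenerate cases fall back to the scalar code path.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import special

logger = logging.getLogger(__name__)

#: sentinel meaning "this CI test could not be computed on this data"
INCOMPUTABLE = None

_SQRT2 = float(np.sqrt(2.0))


@dataclass
class AnalysisConfig:
    """Tuning parameters of the stability-selection run.

    alpha            significance level of each CI test (0.05 or 0.01 by convention)
    iterations       number of bootstrap iterations B (1000 in the emulated study)
    min_count        strict lower bound on the selection count (edge kept iff
                     count > min_count; 500 of 1000 by convention)
    max_cond_size    largest conditioning set searched by the skeleton
    sign_threshold   an edge is called positive when the fraction of selected
                     iterations with a positive partial correlation exceeds this
    ridge            diagonal ridge added to near-singular correlation submatrices
    cond_cap         condition-number threshold that triggers the ridge
    scope            "full" tests every variable pair; "response" restricts the
                     skeleton to pairs involving at least one response/bookkeeping
                     variable
    """

    alpha: float = 0.05
    iterations: int = 1000
    min_count: int = 500
    max_cond_size: int = 3
    sign_threshold: float = 0.5
    ridge: float = 1e-4
    cond_cap: float = 1e8
    scope: str = "full"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not self.min_count < self.iterations:
            raise ValueError("min_count must be < iterations")
        if self.max_cond_size < 0:
            raise ValueError("max_cond_size must be >= 0")
        if self.scope not in ("full", "response"):
            raise ValueError("scope must be 'full' or 'response'")


# ---------------------------------------------------------------------------
# Partial correlation and the conditional-independence test
# ---------------------------------------------------------------------------

class _CorrEngine:
    """Precomputed correlation matrix with partial-correlation queries.

    Built once per dataset (or bootstrap resample); every partial correlation
    is then a small submatrix computation on the cached correlation matrix.
    """

    def __init__(self, data: np.ndarray, ridge: float = 1e-4, cond_cap: float = 1e8):
        self.n, self.p = data.shape
        sd = data.std(axis=0, ddof=1)
        self.degenerate = ~np.isfinite(sd) | (sd == 0)
        safe = np.where(self.degenerate, 1.0, sd)
        z = (data - data.mean(axis=0)) / safe
        self.C = (z.T @ z) / (self.n - 1)
        np.fill_diagonal(self.C, 1.0)
        self.C[self.degenerate, :] = 0.0
        self.C[:, self.degenerate] = 0.0
        self.ridge = ridge
        self.cond_cap = cond_cap

    def pcor(self, i: int, j: int, S: tuple[int, ...]) -> float | None:
        """Partial correlation of columns i, j given S, or INCOMPUTABLE."""
        if self.degenerate[i] or self.degenerate[j] or any(self.degenerate[k] for k in S):
            return INCOMPUTABLE
        C = self.C
        if not S:
            return float(np.clip(C[i, j], -1.0, 1.0))
        if len(S) == 1:
            k = S[0]
            den = (1.0 - C[i, k] ** 2) * (1.0 - C[j, k] ** 2)
            if den > 1e-12:
                r = (C[i, j] - C[i, k] * C[j, k]) / np.sqrt(den)
                return float(np.clip(r, -1.0, 1.0))
            # fall through to the ridge-stabilized matrix route
        idx = np.array((i, j) + tuple(S))
        M = C[np.ix_(idx, idx)]
        cond = np.linalg.cond(M)
        if not np.isfinite(cond) or cond > self.cond_cap:
            M = M + self.ridge * np.eye(len(idx))
        try:
            om = np.linalg.inv(M)
        except np.linalg.LinAlgError:
            try:
                om = np.linalg.inv(M + self.ridge * np.eye(len(idx)))
            except np.linalg.LinAlgError:
                return INCOMPUTABLE
        den = om[0, 0] * om[1, 1]
        if den <= 0:
            return INCOMPUTABLE
        r = -om[0, 1] / np.sqrt(den)
        return float(np.clip(r, -1.0, 1.0))

    def pcor_batch(self, i: int, j: int, sets: list[tuple[int, ...]]) -> np.ndarray:
        """Partial correlations of (i, j) given each conditioning set.

        All sets must have equal size >= 1.  Returns an array with NaN marking
        incomputable entries.  Ill-conditioned or degenerate entries are
        recomputed through the scalar (ridge-stabilized) path so the batched
        route agrees with :meth:`pcor` wherever the latter is defined.
        """
        m = len(sets)
        level = len(sets[0])
        out = np.full(m, np.nan)
        if self.degenerate[i] or self.degenerate[j]:
            return out
        C = self.C
        sets_arr = np.asarray(sets, dtype=int)
        ok = ~self.degenerate[sets_arr].any(axis=1)
        if not ok.any():
            return out
        if level == 1:
            k = sets_arr[:, 0]
            cik, cjk = C[i, k], C[j, k]
            den = (1.0 - cik**2) * (1.0 - cjk**2)
            good = ok & (den > 1e-12)
            with np.errstate(divide="ignore", invalid="ignore"):
                out[good] = np.clip((C[i, j] - cik[good] * cjk[good])
                                    / np.sqrt(den[good]), -1.0, 1.0)
            hard = ok & ~good
        else:
            idxs = np.concatenate(
                [np.broadcast_to([i, j], (m, 2)), sets_arr], axis=1)
            A = C[idxs[:, :, None], idxs[:, None, :]]
            good = ok.copy()
            try:
                om = np.linalg.inv(A[good])
            except np.linalg.LinAlgError:
                om = None
            if om is not None:
                den = om[:, 0, 0] * om[:, 1, 1]
                with np.errstate(divide="ignore", invalid="ignore"):
                    r = -om[:, 0, 1] / np.sqrt(den)
                valid = np.isfinite(r) & (den > 0) & (np.abs(r) <= 1.0 + 1e-9)
                vals = np.full(good.sum(), np.nan)
                vals[valid] = np.clip(r[valid], -1.0, 1.0)
                out[good] = vals
                hard = ok & np.isnan(out)
            else:
                hard = ok
        for pos in np.where(hard)[0]:
            r = self.pcor(i, j, tuple(sets_arr[pos]))
            out[pos] = np.nan if r is INCOMPUTABLE else r
        return out


def _fisher_p(r: float, n: int, s: int) -> float | None:
    dof = n - s - 3
    if dof <= 0:
        return INCOMPUTABLE
    r = float(np.clip(r, -1.0 + 1e-12, 1.0 - 1e-12))
    stat = np.sqrt(dof) * abs(np.arctanh(r))
    return float(special.erfc(stat / _SQRT2))


def _fisher_p_vec(r: np.ndarray, n: int, s: int) -> np.ndarray:
    """Vectorized Fisher-z p-values; NaN propagates (incomputable)."""
    dof = n - s - 3
    if dof <= 0:
        return np.full(np.shape(r), np.nan)
    with np.errstate(invalid="ignore"):
        z = np.abs(np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12)))
        return special.erfc(np.sqrt(dof) * z / _SQRT2)


def partial_correlation(data, i, j, S=(), config: AnalysisConfig | None = None):
    """Partial correlation of columns ``i`` and ``j`` of ``data`` given ``S``.

    ``data`` is a 2-D numeric array or DataFrame; ``i``, ``j`` and the members
    of ``S`` are column indices (or column names for a DataFrame).  With an
    empty conditioning set this is the Pearson correlation.  Returns
    ``INCOMPUTABLE`` (None) when the computation is degenerate (zero-variance
    column, irrecoverably singular submatrix) so callers can apply the
    skip-and-retain fallback instead of aborting.
    """
    config = config or AnalysisConfig()
    X, names = _as_matrix(data)
    i, j, S = _resolve(names, i, j, S)
    if i == j or i in S or j in S:
        raise ValueError("columns i, j and the conditioning set must be distinct")
    if X.shape[0] < len(S) + 3:
        raise ValueError("need at least |S| + 3 rows")
    eng = _CorrEngine(X, ridge=config.ridge, cond_cap=config.cond_cap)
    return eng.pcor(i, j, tuple(S))


def ci_test(data, i, j, S=(), config: AnalysisConfig | None = None):
    """Fisher-z conditional-independence test; returns a p-value or INCOMPUTABLE.

    The statistic is sqrt(n - |S| - 3) * |atanh(r)| referred to the standard
    normal, two-sided; r = 0 gives p = 1.  Insufficient sample
    (n - |S| - 3 <= 0) and degenerate inputs propagate the incomputable signal.
    """
    config = config or AnalysisConfig()
    X, names = _as_matrix(data)
    i, j, S = _resolve(names, i, j, S)
    n = X.shape[0]
    if n - len(S) - 3 <= 0:
        return INCOMPUTABLE
    r = partial_correlation(X, i, j, S, config)
    if r is INCOMPUTABLE:
        return INCOMPUTABLE
    return _fisher_p(r, n, len(S))


def _as_matrix(data) -> tuple[np.ndarray, list | None]:
    if isinstance(data, pd.DataFrame):
        if not all(np.issubdtype(dt, np.number) for dt in data.dtypes):
            raise TypeError("data must be numeric")
        return data.to_numpy(dtype=float), list(data.columns)
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise TypeError("data must be a 2-D numeric matrix")
    return X, None


def _resolve(names, i, j, S):
    if names is not None and isinstance(i, str):
        i, j = names.index(i), names.index(j)
        S = tuple(names.index(s) for s in S)
    return int(i), int(j), tuple(int(s) for s in S)


# ---------------------------------------------------------------------------
# PC skeleton
# ---------------------------------------------------------------------------

def pc_skeleton(data, config: AnalysisConfig | None = None,
                names: list[str] | None = None,
                _quiet: bool = False) -> nx.Graph:
    """PC-algorithm skeleton of the conditional-independence structure.

    Starts from the complete graph (restricted to response-incident pairs when
    ``config.scope == "response"``) and removes edge (i, j) as soon as some
    conditioning set S drawn from the current neighbours of i or of j, of size
    0 .. ``max_cond_size`` enumerated in increasing size and lexicographic
    order within a size, yields a test p-value above alpha.  Incomputable
    tests are skipped with the edge retained for that set.  Constant columns
    are isolated up front (graph attribute ``isolated``).

    Each surviving edge carries its last surviving partial correlation in the
    ``pcor`` edge attribute (the sign source for stability voting).
    """
    config = config or AnalysisConfig()
    X, auto_names = _as_matrix(data)
    if names is None:
        names = auto_names or [f"x{k}" for k in range(X.shape[1])]
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least 2 columns")
    if n < config.max_cond_size + 3:
        raise ValueError("need at least max_cond_size + 3 rows")

    eng = _CorrEngine(X, ridge=config.ridge, cond_cap=config.cond_cap)
    isolated = [names[k] for k in np.where(eng.degenerate)[0]]
    if isolated:
        log = logger.debug if _quiet else logger.warning
        log("isolating %d constant column(s): %s", len(isolated), isolated)
    alive = np.where(~eng.degenerate)[0]

    if config.scope == "response":
        resp = {k for k, nm in enumerate(names) if _is_response_node(nm)}
    else:
        resp = None

    g = nx.Graph()
    g.add_nodes_from(names)
    g.graph["isolated"] = isolated
    g.graph["incomputable_tests"] = 0

    # level 0: all pairwise tests from the correlation matrix, vectorized
    alive = alive[np.argsort([names[k] for k in alive])]
    adj: dict[int, set[int]] = {k: set() for k in alive}
    if n - 3 <= 0:
        g.graph["incomputable_tests"] = len(alive) * (len(alive) - 1) // 2
        return g
    P = _fisher_p_vec(eng.C, n, 0)
    pcor_last: dict[frozenset, float] = {}
    for a_pos in range(len(alive)):
        for b_pos in range(a_pos + 1, len(alive)):
            i, j = alive[a_pos], alive[b_pos]
            if resp is not None and i not in resp and j not in resp:
                continue
            if P[i, j] <= config.alpha:
                adj[i].add(j)
                adj[j].add(i)
                pcor_last[frozenset((i, j))] = float(eng.C[i, j])

    # levels 1 .. max_cond_size; adjacency is updated as edges are removed
    for level in range(1, config.max_cond_size + 1):
        edges = sorted({frozenset((i, j)) for i in adj for j in adj[i]},
                       key=lambda e: tuple(sorted(names[k] for k in e)))
        any_testable = False
        for e in edges:
            i, j = sorted(e, key=lambda k: names[k])
            if j not in adj[i]:
                continue  # removed earlier this level
            cand: list[tuple[int, ...]] = []
            seen: set[tuple[int, ...]] = set()
            for base in (i, j):
                other = j if base == i else i
                nbrs = sorted(adj[base] - {other}, key=lambda k: names[k])
                for S in itertools.combinations(nbrs, level):
                    if S not in seen:
                        seen.add(S)
                        cand.append(S)
            if not cand:
                continue
            any_testable = True
            rs = eng.pcor_batch(i, j, cand)
            ps = _fisher_p_vec(rs, n, level)
            incomputable = np.isnan(ps)
            g.graph["incomputable_tests"] += int(incomputable.sum())
            removers = np.where(~incomputable & (ps > config.alpha))[0]
            if removers.size:
                adj[i].discard(j)
                adj[j].discard(i)
                pcor_last.pop(e, None)
            else:
                valid = np.where(~incomputable)[0]
                if valid.size:
                    pcor_last[e] = float(rs[valid[-1]])
        if not any_testable:
            break

    for e, r in pcor_last.items():
        i, j = tuple(e)
        g.add_edge(names[i], names[j], pcor=r)
    return g


def _is_response_node(name: str) -> bool:
    return name in ("os_days", "ttf_days", "psa_response",
                    "os_censoring", "ttf_censoring", "observation_days",
                    "os_event", "ttf_event")


# ---------------------------------------------------------------------------
# Bootstrap stability selection
# ---------------------------------------------------------------------------

@dataclass
class StabilityResult:
    """Per-pair selection and sign counts over B bootstrap iterations."""

    alpha: float
    B: int
    counts: dict[frozenset, list[int]] = field(default_factory=dict)  # pair -> [sel, pos]
    failures: list[tuple[int, str]] = field(default_factory=list)

    def selection_count(self, a: str, b: str) -> int:
        return self.counts.get(frozenset((a, b)), [0, 0])[0]

    def frequency(self, a: str, b: str) -> float:
        return self.selection_count(a, b) / self.B

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pair, (sel, pos) in self.counts.items():
            a, b = sorted(pair)
            rows.append({
                "source": a, "target": b,
                "count": sel, "B": self.B,
                "frequency": sel / self.B,
                "positive_fraction": pos / sel if sel else float("nan"),
            })
        df = pd.DataFrame(rows, columns=["source", "target", "count", "B",
                                         "frequency", "positive_fraction"])
        return df.sort_values(["frequency", "source", "target"],
                              ascending=[False, True, True]).reset_index(drop=True)


def stability_run(table: pd.DataFrame,
                  config: AnalysisConfig | None = None) -> StabilityResult:
    """Bootstrap stability selection over PC skeletons.

    For b = 1..B, resample the patients with replacement (same n), estimate
    the PC skeleton on the resample, and count for every unordered pair how
    often its edge is present and how often its surviving partial correlation
    is positive.  An iteration that fails outright is logged and counted as
    contributing no edges; the run never aborts.  Deterministic given
    ``config.seed``.
    """
    config = config or AnalysisConfig()
    X, names = _as_matrix(table)
    if names is None:
        names = [f"x{k}" for k in range(X.shape[1])]
    n = X.shape[0]
    rng = np.random.default_rng(config.seed)
    result = StabilityResult(alpha=config.alpha, B=config.iterations)
    for b in range(config.iterations):
        idx = rng.integers(0, n, size=n)
        try:
            skel = pc_skeleton(X[idx], config, names=names, _quiet=True)
        except Exception as exc:  # noqa: BLE001 - deliberate: one bad draw must not abort
            logger.warning("bootstrap iteration %d failed: %s", b, exc)
            result.failures.append((b, str(exc)))
            continue
        for a, c, attrs in skel.edges(data=True):
            rec = result.counts.setdefault(frozenset((a, c)), [0, 0])
            rec[0] += 1
            if attrs.get("pcor", 0.0) > 0:
                rec[1] += 1
    return result


@dataclass(frozen=True)
class EdgeCall:
    pair: frozenset
    frequency: float
    sign: str  # positive | negative | indeterminate


@dataclass
class EdgeSelection:
    """Stable edges: pairs selected in more than ``min_count`` iterations."""

    alpha: float
    B: int
    min_count: int
    edges: list[EdgeCall]

    def pairs(self) -> set[frozenset]:
        return {e.pair for e in self.edges}

    def to_frame(self) -> pd.DataFrame:
        rows = [{"source": min(e.pair), "target": max(e.pair),
                 "frequency": e.frequency, "sign": e.sign} for e in self.edges]
        df = pd.DataFrame(rows, columns=["source", "target", "frequency", "sign"])
        return df.sort_values(["frequency", "source", "target"],
                              ascending=[False, True, True]).reset_index(drop=True)


def select_stable_edges(result: StabilityResult,
                        config: AnalysisConfig | None = None) -> EdgeSelection:
    """Apply the strict supermajority rule to a stability result.

    A pair is retained iff its selection count is strictly greater than
    ``config.min_count``.  Its sign is positive when the positive fraction
    among selected iterations strictly exceeds ``sign_threshold``, negative
    when strictly below ``1 - sign_threshold``, else indeterminate (an exact
    tie at the threshold is indeterminate).
    """
    config = config or AnalysisConfig()
    if result.B != config.iterations:
        raise ValueError("result.B does not match config.iterations")
    calls = []
    for pair, (sel, pos) in result.counts.items():
        if sel > config.min_count:
            frac = pos / sel
            if frac > config.sign_threshold:
                sign = "positive"
            elif frac < 1.0 - config.sign_threshold:
                sign = "negative"
            else:
                sign = "indeterminate"
            calls.append(EdgeCall(pair=pair, frequency=sel / result.B, sign=sign))
    calls.sort(key=lambda e: (-e.frequency, tuple(sorted(e.pair))))
    return EdgeSelection(alpha=result.alpha, B=result.B,
                         min_count=config.min_count, edges=calls)
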