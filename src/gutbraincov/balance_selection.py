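"""Forward selection of the balance most predictive of a continuous phenotype.

The search starts from the single pair of taxa whose balance has the
highest coefficient of determination against the response, then greedily
adds one taxon at a time to either side of the balance, keeping the
addition that most improves the R^2 of an ordinary least-squares fit of
``response ~ intercept (+ covariates) + balance``.  Repeated k-fold
cross-validation picks the signature size by the one-standard-error rule
on held-out mean squared error and tabulates how often each taxon and
each candidate balance is selected, which is the practical measure of
the signature's robustness.

All tie-breaks are deterministic: candidates are compared by score, then
by positive orientation of the balance against the response, then
lexicographically by taxon id with the numerator side first.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.model_selection import RepeatedKFold

from .compositional import AbundanceTable, BalanceSignature, _LOG_BASES, compute_balance

__all__ = [
    "DegenerateRegressorError",
    "SelectionTrace",
    "RobustnessTable",
    "CVResult",
    "score_balance",
    "select_first_pair",
    "forward_select",
    "cross_validate_signature",
    "ForwardBalanceSelector",
    "CrossValidatedBalanceSelector",
]


class DegenerateRegressorError(ValueError):
    """The balance (or another regressor) is constant across samples."""


# ---------------------------------------------------------------------------
# scoring


def _covariate_basis(n: int, covariates: np.ndarray | None) -> np.ndarray:
    """Orthonormal basis of [intercept, covariates]."""
    if covariates is None:
        cols = np.ones((n, 1))
    else:
        covariates = np.atleast_2d(np.asarray(covariates, float))
        if covariates.shape[0] != n:
            covariates = covariates.T
        cols = np.column_stack([np.ones(n), covariates])
    q, _ = np.linalg.qr(cols)
    return q


def score_balance(
    balance_values: np.ndarray,
    response: np.ndarray,
    covariates: np.ndarray | None = None,
) -> float:
    """R^2 of an OLS fit of ``response`` on [intercept, covariates, balance].

    A constant response returns 0.0; a balance that is constant (after
    projecting out intercept and covariates) raises
    :class:`DegenerateRegressorError`.
    """
    b = np.asarray(balance_values, float)
    y = np.asarray(response, float)
    if b.shape != y.shape:
        raise ValueError("balance and response must have equal length")
    n = y.size
    q = _covariate_basis(n, covariates)
    yr = y - q @ (q.T @ y)
    br = b - q @ (q.T @ b)
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        return 0.0
    bb = float(br @ br)
    if bb <= 1e-12 * max(1.0, float(b @ b)):
        raise DegenerateRegressorError("balance is constant given the covariates")
    rss_cov = float(yr @ yr)
    rss_full = rss_cov - float(br @ yr) ** 2 / bb
    return 1.0 - rss_full / tss


def _score_candidates(
    cand: np.ndarray, q: np.ndarray, yr: np.ndarray, tss: float
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized full-model R^2 for candidate balance columns.

    Returns (scores, corr_sign) with degenerate candidates scored -inf.
    """
    cr = cand - q @ (q.T @ cand)
    bb = np.einsum("ij,ij->j", cr, cr)
    by = cr.T @ yr
    rss_cov = float(yr @ yr)
    with np.errstate(divide="ignore", invalid="ignore"):
        rss_full = rss_cov - by**2 / bb
        scores = 1.0 - rss_full / tss
    norms = np.einsum("ij,ij->j", cand, cand)
    bad = bb <= 1e-12 * np.maximum(1.0, norms)
    scores[bad] = -np.inf
    return scores, np.sign(by)


def _log_matrix(table: AbundanceTable, log_base) -> np.ndarray:
    if np.any(table.values <= 0):
        raise ValueError("table must be strictly positive; apply replace_zeros first")
    return np.log(table.values) / math.log(_LOG_BASES[log_base])


# ---------------------------------------------------------------------------
# traces and results


@dataclass(frozen=True)
class SelectionStep:
    taxon: str
    side: str  # 'A' (numerator) or 'B' (denominator)
    score_after: float


@dataclass
class SelectionTrace:
    """Accepted path of a forward search plus every candidate score evaluated."""

    steps: list[SelectionStep] = field(default_factory=list)
    candidate_scores: list[dict[tuple[str, str], float]] = field(default_factory=list)
    log_base: str | int = "e"
    use_ilr_coefficient: bool = False

    def signature_at_size(self, size: int) -> BalanceSignature:
        """Signature from the first ``size`` accepted taxa (size >= 2)."""
        if size < 2 or size > len(self.steps):
            raise ValueError(f"size must be in [2, {len(self.steps)}]")
        num = tuple(s.taxon for s in self.steps[:size] if s.side == "A")
        den = tuple(s.taxon for s in self.steps[:size] if s.side == "B")
        return BalanceSignature(
            num, den, self.log_base, self.use_ilr_coefficient,
            score=self.steps[size - 1].score_after,
        )

    @property
    def sizes(self) -> list[int]:
        return list(range(2, len(self.steps) + 1))


@dataclass
class RobustnessTable:
    """Cross-validation selection frequencies and held-out score profile."""

    per_taxon_frequency: pd.Series
    per_balance_frequency: pd.Series
    cv_score_by_size: pd.DataFrame

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# per-taxon selection frequency\n")
            self.per_taxon_frequency.rename_axis("taxon").rename("frequency").to_csv(
                fh, sep="\t", header=True
            )
            fh.write("# per-balance selection frequency\n")
            self.per_balance_frequency.rename_axis("balance").rename("frequency").to_csv(
                fh, sep="\t", header=True
            )
            fh.write("# held-out error by signature size\n")
            self.cv_score_by_size.to_csv(fh, sep="\t", index_label="size")


@dataclass
class CVResult:
    optimal_size: int
    robustness: RobustnessTable
    signature: BalanceSignature
    trace: SelectionTrace


# ---------------------------------------------------------------------------
# search


_TIE_TOL = 1e-10  # R^2 differences below this count as exact ties


def _pick_best(names, scores, signs, current_best=-np.inf):
    """Deterministic argmax: score, then positive orientation, then the
    candidate order (which callers construct lexicographically).  Scores
    within ``_TIE_TOL`` are treated as tied so floating-point noise
    cannot override the deterministic tie rules."""
    best_i, best_s, best_pos = None, current_best, False
    for i, (s, g) in enumerate(zip(scores, signs)):
        pos = g > 0
        if s > best_s + _TIE_TOL:
            best_i, best_s, best_pos = i, s, pos
        elif best_i is not None and s > best_s - _TIE_TOL and pos and not best_pos:
            best_i, best_s, best_pos = i, max(s, best_s), pos
    return best_i, best_s


def select_first_pair(
    table: AbundanceTable,
    response: np.ndarray,
    covariates: np.ndarray | None = None,
    log_base="e",
    use_ilr_coefficient: bool = False,
) -> BalanceSignature:
    """Exhaustively score every ordered taxon pair (i in A, j in B) and
    return the best single-pair balance."""
    if table.n_taxa < 2:
        raise ValueError("need at least two taxa")
    y = np.asarray(response, float)
    L = _log_matrix(table, log_base)
    n = table.n_samples
    q = _covariate_basis(n, covariates)
    yr = y - q @ (q.T @ y)
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        raise DegenerateRegressorError("response is constant")

    order = sorted(range(table.n_taxa), key=lambda i: table.taxon_ids[i])
    names, cols = [], []
    for i in order:
        for j in order:
            if i == j:
                continue
            names.append((table.taxon_ids[i], table.taxon_ids[j]))
            cols.append(L[:, i] - L[:, j])
    cand = np.column_stack(cols)
    scores, signs = _score_candidates(cand, q, yr, tss)
    best_i, best_s = _pick_best(names, scores, signs)
    if best_i is None:
        raise DegenerateRegressorError("all candidate pair balances are degenerate")
    a, b = names[best_i]
    return BalanceSignature((a,), (b,), log_base, use_ilr_coefficient, score=float(best_s))


def forward_select(
    table: AbundanceTable,
    response: np.ndarray,
    max_size: int = 8,
    min_improvement: float = 1e-4,
    covariates: np.ndarray | None = None,
    log_base="e",
    use_ilr_coefficient: bool = False,
) -> tuple[BalanceSignature, SelectionTrace]:
    """Greedy forward search for the most predictive balance.

    Starting from :func:`select_first_pair`, each round scores every
    remaining taxon on each side and accepts the single best addition if
    it improves the R^2 by at least ``min_improvement`` (use 0.0 to grow
    the path to ``max_size`` whenever any non-worsening addition
    exists).  Degenerate candidates are skipped and recorded with score
    ``-inf`` in the trace.
    """
    y = np.asarray(response, float)
    L = _log_matrix(table, log_base)
    n = table.n_samples
    q = _covariate_basis(n, covariates)
    yr = y - q @ (q.T @ y)
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        raise DegenerateRegressorError("response is constant")

    first = select_first_pair(table, y, covariates, log_base, use_ilr_coefficient)
    trace = SelectionTrace(log_base=log_base, use_ilr_coefficient=use_ilr_coefficient)
    trace.steps.append(SelectionStep(first.numerator[0], "A", first.score))
    trace.steps.append(SelectionStep(first.denominator[0], "B", first.score))
    trace.candidate_scores.append({})
    trace.candidate_scores.append({})

    in_a = [first.numerator[0]]
    in_b = [first.denominator[0]]
    cur_score = first.score
    idx = {t: i for i, t in enumerate(table.taxon_ids)}

    while len(in_a) + len(in_b) < min(max_size, table.n_taxa):
        used = set(in_a) | set(in_b)
        remaining = sorted(t for t in table.taxon_ids if t not in used)
        if not remaining:
            break
        ia = [idx[t] for t in in_a]
        ib = [idx[t] for t in in_b]
        ma = L[:, ia].mean(axis=1)
        mb = L[:, ib].mean(axis=1)
        names, cols = [], []
        for t in remaining:  # lexicographic; A side first per taxon
            lt = L[:, idx[t]]
            names.append((t, "A"))
            cols.append((ma * len(ia) + lt) / (len(ia) + 1) - mb)
            names.append((t, "B"))
            cols.append(ma - (mb * len(ib) + lt) / (len(ib) + 1))
        cand = np.column_stack(cols)
        scores, signs = _score_candidates(cand, q, yr, tss)
        trace.candidate_scores.append(
            {nm: float(s) for nm, s in zip(names, scores)}
        )
        best_i, best_s = _pick_best(names, scores, signs)
        if best_i is None or not np.isfinite(best_s):
            trace.candidate_scores.pop()
            break
        if best_s - cur_score < min_improvement:
            trace.candidate_scores.pop()
            break
        t, side = names[best_i]
        (in_a if side == "A" else in_b).append(t)
        cur_score = float(best_s)
        trace.steps.append(SelectionStep(t, side, cur_score))

    sig = BalanceSignature(
        tuple(in_a), tuple(in_b), log_base, use_ilr_coefficient, score=cur_score
    )
    return sig, trace


# ---------------------------------------------------------------------------
# cross-validation


def _one_se_size(cv_tab: pd.DataFrame) -> int:
    """Smallest size whose mean held-out MSE is within one standard error
    of the minimum."""
    best = cv_tab["mean_mse"].idxmin()
    cutoff = cv_tab.loc[best, "mean_mse"] + cv_tab.loc[best, "se_mse"]
    ok = cv_tab.index[cv_tab["mean_mse"] <= cutoff]
    return int(ok.min())


def cross_validate_signature(
    table: AbundanceTable,
    response: np.ndarray,
    covariates: np.ndarray | None = None,
    folds: int = 5,
    repeats: int = 10,
    max_size: int = 8,
    rng_seed: int = 0,
    log_base="e",
    use_ilr_coefficient: bool = False,
) -> CVResult:
    """Repeated k-fold CV around the forward search.

    Within every training split the forward path is grown to
    ``max_size`` (``min_improvement=0``), each nested signature size is
    scored by held-out MSE, and the overall size is chosen by the
    one-standard-error rule.  Selection frequencies are tabulated over
    the per-split signatures truncated to that size.  The reported
    signature is the full-data forward path truncated likewise.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    y = np.asarray(response, float)
    cov = None if covariates is None else np.asarray(covariates, float)
    n = table.n_samples

    rkf = RepeatedKFold(n_splits=folds, n_repeats=repeats, random_state=rng_seed)
    mse_records: list[dict] = []
    fold_traces: list[SelectionTrace] = []
    for tr, te in rkf.split(np.arange(n)):
        y_tr, y_te = y[tr], y[te]
        if np.ptp(y_tr) == 0:
            warnings.warn("skipping CV fold with constant training response")
            continue
        sub_tr = AbundanceTable(
            [table.sample_ids[i] for i in tr], list(table.taxon_ids), table.values[tr]
        )
        sub_te = AbundanceTable(
            [table.sample_ids[i] for i in te], list(table.taxon_ids), table.values[te]
        )
        cov_tr = None if cov is None else cov[tr]
        cov_te = None if cov is None else cov[te]
        _, trace = forward_select(
            sub_tr, y_tr, max_size=max_size, min_improvement=0.0,
            covariates=cov_tr, log_base=log_base,
            use_ilr_coefficient=use_ilr_coefficient,
        )
        fold_traces.append(trace)
        for size in trace.sizes:
            sig = trace.signature_at_size(size)
            b_tr = compute_balance(sub_tr, sig)
            b_te = compute_balance(sub_te, sig)
            x_tr = np.column_stack(
                [np.ones(len(tr))] + ([] if cov_tr is None else [cov_tr]) + [b_tr]
            )
            x_te = np.column_stack(
                [np.ones(len(te))] + ([] if cov_te is None else [cov_te]) + [b_te]
            )
            beta, *_ = np.linalg.lstsq(x_tr, y_tr, rcond=None)
            mse = float(np.mean((y_te - x_te @ beta) ** 2))
            mse_records.append({"size": size, "mse": mse})

    if not mse_records:
        raise ValueError("no usable CV folds")
    mse_df = pd.DataFrame(mse_records)
    cv_tab = mse_df.groupby("size")["mse"].agg(
        mean_mse="mean", se_mse=lambda v: v.std(ddof=1) / np.sqrt(len(v)), n_fits="count"
    )
    optimal_size = _one_se_size(cv_tab)

    taxon_counts = pd.Series(0.0, index=list(table.taxon_ids))
    balance_counts: dict[str, int] = {}
    n_fits = 0
    for trace in fold_traces:
        size = min(optimal_size, len(trace.steps))
        sig = trace.signature_at_size(size)
        n_fits += 1
        for t in sig.numerator + sig.denominator:
            taxon_counts[t] += 1
        balance_counts[sig.key()] = balance_counts.get(sig.key(), 0) + 1
    per_taxon = taxon_counts / n_fits
    per_balance = pd.Series(balance_counts, dtype=float).sort_values(ascending=False) / n_fits

    sig_full, trace_full = forward_select(
        table, y, max_size=max_size, min_improvement=0.0,
        covariates=cov, log_base=log_base, use_ilr_coefficient=use_ilr_coefficient,
    )
    final_size = min(optimal_size, len(trace_full.steps))
    signature = trace_full.signature_at_size(final_size)
    rob = RobustnessTable(per_taxon, per_balance, cv_tab)
    return CVResult(optimal_size, rob, signature, trace_full)


# ---------------------------------------------------------------------------
# sklearn estimators


class ForwardBalanceSelector(BaseEstimator, TransformerMixin):
    """Greedy balance selection as a scikit-learn transformer.

    ``fit(X, y)`` runs the forward search on an abundance matrix
    (DataFrame with taxon columns, or array plus ``taxon_ids``);
    ``transform(X)`` returns the fitted balance as a single-column
    feature.

    Attributes
    ----------
    signature_ : BalanceSignature
    trace_ : SelectionTrace
    score_ : float
        In-sample R^2 of the selected balance.
    """

    def __init__(
        self,
        max_size: int = 8,
        min_improvement: float = 1e-4,
        log_base="e",
        use_ilr_coefficient: bool = False,
        taxon_ids: list[str] | None = None,
    ):
        self.max_size = max_size
        self.min_improvement = min_improvement
        self.log_base = log_base
        self.use_ilr_coefficient = use_ilr_coefficient
        self.taxon_ids = taxon_ids

    def _as_table(self, X) -> AbundanceTable:
        if isinstance(X, AbundanceTable):
            return X
        if isinstance(X, pd.DataFrame):
            return AbundanceTable.from_dataframe(X)
        X = np.asarray(X, float)
        ids = self.taxon_ids or [f"t{i:02d}" for i in range(X.shape[1])]
        return AbundanceTable([f"s{i}" for i in range(X.shape[0])], list(ids), X)

    def fit(self, X, y):
        table = self._as_table(X)
        self.signature_, self.trace_ = forward_select(
            table, np.asarray(y, float), self.max_size, self.min_improvement,
            log_base=self.log_base, use_ilr_coefficient=self.use_ilr_coefficient,
        )
        self.score_ = self.signature_.score
        return self

    def transform(self, X):
        return compute_balance(self._as_table(X), self.signature_)[:, None]


class CrossValidatedBalanceSelector(ForwardBalanceSelector):
    """Balance selection with CV-chosen signature size and robustness table.

    Attributes (after fit): ``signature_``, ``optimal_size_``,
    ``robustness_``, ``trace_``.
    """

    def __init__(
        self,
        max_size: int = 8,
        folds: int = 5,
        repeats: int = 10,
        rng_seed: int = 0,
        log_base="e",
        use_ilr_coefficient: bool = False,
        taxon_ids: list[str] | None = None,
    ):
        super().__init__(max_size=max_size, log_base=log_base,
                         use_ilr_coefficient=use_ilr_coefficient, taxon_ids=taxon_ids)
        self.folds = folds
        self.repeats = repeats
        self.rng_seed = rng_seed

    def fit(self, X, y):
        table = self._as_table(X)
        res = cross_validate_signature(
            table, np.asarray(y, float), folds=self.folds, repeats=self.repeats,
            max_size=self.max_size, rng_seed=self.rng_seed, log_base=self.log_base,
            use_ilr_coefficient=self.use_ilr_coefficient,
        )
        self.signature_ = res.signature
        self.optimal_size_ = res.optimal_size
        self.robustness_ = res.robustness
        self.trace_ = res.trace
        self.score_ = res.signature.score
        return self
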