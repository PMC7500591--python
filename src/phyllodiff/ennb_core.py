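"""Two-stage differential-abundance testing for annotation count tables.

Stage 1 screens annotations with a cross-validated elastic-net logistic
regression of treatment on transformed abundances; stage 2 fits a
negative-binomial GLM (log link, treatment as the sole factor, library-size
offsets) per selected annotation and tests the treatment coefficient.
Between-sample normalization is either TMM (trimmed mean of M-values,
method 1) or DESeq-type median-of-ratios size factors (method 2), both
reimplemented here from their standard definitions.

Only one experimental factor can be fitted; analyses are run one field
site at a time.  No multiple-testing correction is applied within a run:
the operating alpha is calibrated by simulation (see
:mod:`phyllodiff.calibration`), with Benjamini-Hochberg available as an
optional extra.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats
from sklearn.linear_model import LogisticRegression

from .io_preprocess import CountTable, drop_zero_rows, impute_replicate

logger = logging.getLogger("phyllodiff")

DEFAULT_TRIM_LOGRATIO = 0.3
DEFAULT_TRIM_ABS = 0.05
DEFAULT_MIXING = 0.5
#: Inverse-regularization grid for the elastic-net stage (sklearn C scale).
DEFAULT_C_GRID = tuple(np.logspace(-3, 2, 16))
DISPERSION_FLOOR = 1e-8
#: Leave-one-out cross-validation below this total sample count, else 5-fold.
LOO_MAX_N = 8


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalizationFactors:
    """Per-sample positive scale factors from TMM or median-of-ratios."""

    factors: pd.Series
    method: str  # "tmm" | "deseq"

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("normalization factors must all be positive")


def _counts_frame(table) -> pd.DataFrame:
    return table.counts if isinstance(table, CountTable) else pd.DataFrame(table)


def tmm_factors(
    table,
    trim_logratio: float = DEFAULT_TRIM_LOGRATIO,
    trim_abs: float = DEFAULT_TRIM_ABS,
    ref_sample: str | None = None,
) -> NormalizationFactors:
    """Trimmed mean of M-values normalization factors.

    For each sample against the reference column (the highest-depth sample
    by default), genes positive in both are ranked by log2 ratio of
    proportions (M) and by average log2 proportion (A); ``trim_logratio``
    and ``trim_abs`` are trimmed from each tail of M and A respectively,
    and the factor is two to the precision-weighted mean of the surviving
    M values.  Factors are rescaled to geometric mean one.
    """
    counts = _counts_frame(table)
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    totals = counts.sum(axis=0)
    zero_samples = totals.index[totals <= 0].tolist()
    if zero_samples:
        raise ValueError(f"samples with all-zero counts: {zero_samples}")
    if ref_sample is None:
        ref_sample = totals.idxmax()
    yr = counts[ref_sample].to_numpy(dtype=float)
    nr = float(totals[ref_sample])

    factors = {}
    for s in counts.columns:
        if s == ref_sample:
            factors[s] = 1.0
            continue
        yk = counts[s].to_numpy(dtype=float)
        nk = float(totals[s])
        pos = (yk > 0) & (yr > 0)
        if not pos.any():
            raise ValueError(f"no annotation positive in both {s} and {ref_sample}")
        pk, pr = yk[pos] / nk, yr[pos] / nr
        m = np.log2(pk / pr)
        a = 0.5 * np.log2(pk * pr)
        # asymptotic (binomial) variance of M; weight is its inverse
        v = (nk - yk[pos]) / (nk * yk[pos]) + (nr - yr[pos]) / (nr * yr[pos])
        n = m.size
        lo_m = int(np.floor(n * trim_logratio)) + 1
        lo_a = int(np.floor(n * trim_abs)) + 1
        rm = stats.rankdata(m)
        ra = stats.rankdata(a)
        keep = (rm >= lo_m) & (rm <= n + 1 - lo_m) & (ra >= lo_a) & (ra <= n + 1 - lo_a)
        if not keep.any():
            factors[s] = 1.0
            continue
        w = 1.0 / v[keep]
        factors[s] = float(2.0 ** (np.sum(w * m[keep]) / np.sum(w)))

    f = pd.Series(factors)[counts.columns]
    f /= np.exp(np.mean(np.log(f)))
    return NormalizationFactors(f, "tmm")


def deseq_size_factors(table, fallback: bool = True) -> NormalizationFactors:
    """Median-of-ratios (DESeq-type) size factors.

    ``factor_j = median_i(count_ij / geometric-mean_i)`` over annotations
    with positive counts in every sample.  If no annotation is positive
    everywhere and ``fallback`` is on, the geometric mean is taken over
    positive entries only (annotations positive in at least two samples).
    """
    counts = _counts_frame(table)
    arr = counts.to_numpy(dtype=float)
    all_pos = (arr > 0).all(axis=1)
    if all_pos.any():
        sub = arr[all_pos]
        log_gm = np.mean(np.log(sub), axis=1)
        ratios = np.log(sub) - log_gm[:, None]
    elif fallback:
        npos = (arr > 0).sum(axis=1)
        use = npos >= 2
        if not use.any():
            raise ValueError("no annotation positive in >= 2 samples")
        sub = arr[use]
        with np.errstate(divide="ignore"):
            logs = np.where(sub > 0, np.log(sub), np.nan)
        log_gm = np.nanmean(logs, axis=1)
        ratios = logs - log_gm[:, None]
    else:
        raise ValueError("no annotation positive in every sample and fallback disabled")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(ratios, axis=0)
    f = pd.Series(np.exp(med), index=counts.columns)
    if (~np.isfinite(f) | (f <= 0)).any():
        raise ValueError("degenerate size factors; check for empty samples")
    return NormalizationFactors(f, "deseq")


# ---------------------------------------------------------------------------
# stage 1: elastic-net screening
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SelectionResult:
    """Annotations surviving the elastic-net screen, with the chosen penalty."""

    selected: tuple[str, ...]
    lambda_: float          # inverse of the sklearn C actually used
    mixing: float
    cv_rule: str
    seed: int
    dropped_constant: tuple[str, ...] = ()


def _treatment_vector(labels) -> np.ndarray:
    labs = pd.Series(labels)
    levels = sorted(labs.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two treatment levels, got {levels}")
    # "watered" is the reference when present
    if "watered" in levels:
        ref = "watered"
    else:
        ref = levels[0]
    return (labs != ref).to_numpy(dtype=int)


def elastic_net_select(
    counts: pd.DataFrame,
    treatment_labels,
    mixing: float = DEFAULT_MIXING,
    n_folds: int | None = None,
    seed: int = 0,
    cv_rule: str = "1se",
    c_grid=DEFAULT_C_GRID,
    rel_factors: pd.Series | None = None,
) -> SelectionResult:
    """Cross-validated elastic-net screen of annotations.

    Fits a penalized binomial regression of treatment on
    ``log(normalized count + 1)`` abundances (annotations standardized),
    choosing the penalty by cross-validated deviance - leave-one-out when
    the design has <= 8 samples, else ``n_folds``-fold (default 5).  The
    default ``cv_rule="1se"`` takes the strongest penalty within one
    standard error of the deviance minimum (the glmnet convention), which
    keeps the screen sparse at the 3-per-group sizes this pipeline
    targets; ``"min"`` takes the minimizer itself.  Returns the annotations
    with nonzero coefficients.

    ``rel_factors`` are per-sample relative depth factors (geometric mean
    one) used to normalize the predictors; left unset, column totals are
    used, so that sequencing depth cannot masquerade as a treatment
    signal.
    """
    if not 0.0 <= mixing <= 1.0:
        raise ValueError("mixing must lie in [0, 1]")
    y = _treatment_vector(treatment_labels)
    n = len(y)
    if min((y == 0).sum(), (y == 1).sum()) < 3:
        raise ValueError(
            "need >= 3 samples per group for cross-validated selection; "
            "impute a replicate for 2-sample groups first")

    X = counts.to_numpy(dtype=float).T  # samples x annotations
    if rel_factors is None:
        totals = X.sum(axis=1)
        if (totals <= 0).any():
            raise ValueError("a sample has zero total count")
        rel = totals / np.exp(np.mean(np.log(totals)))
    else:
        rel = rel_factors.to_numpy(dtype=float)
    X = X / rel[:, None]
    X = np.log1p(X)
    sd = X.std(axis=0)
    keep = sd > 0
    dropped = tuple(counts.index[~keep])
    if dropped:
        logger.info("elastic net: dropped %d constant annotations", len(dropped))
    if not keep.any():
        warnings.warn("all predictors constant; empty selection", stacklevel=2)
        return SelectionResult((), float("inf"), mixing, cv_rule, seed, dropped)
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]

    if n <= LOO_MAX_N:
        folds = [(np.arange(n) != i, np.arange(n) == i) for i in range(n)]
    else:
        k = n_folds or 5
        rng = np.random.default_rng(seed)
        assign = rng.permutation(n) % k
        folds = [(assign != j, assign == j) for j in range(k)]

    c_grid = np.asarray(sorted(c_grid))

    def _fit(C, rows, max_iter=3000, tol=1e-3):
        clf = LogisticRegression(
            C=C, penalty="elasticnet", solver="saga", l1_ratio=mixing,
            max_iter=max_iter, tol=tol, random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(Xs[rows], y[rows])
        return clf

    dev = np.zeros((len(c_grid), len(folds)))
    for ci, C in enumerate(c_grid):
        for fi, (tr, te) in enumerate(folds):
            if len(np.unique(y[tr])) < 2:
                dev[ci, fi] = np.nan
                continue
            clf = _fit(C, tr)
            p = np.clip(clf.predict_proba(Xs[te])[:, 1], 1e-12, 1 - 1e-12)
            dev[ci, fi] = -np.mean(y[te] * np.log(p) + (1 - y[te]) * np.log(1 - p))
    mean = np.nanmean(dev, axis=1)
    se = np.nanstd(dev, axis=1, ddof=1) / np.sqrt(dev.shape[1])
    best = int(np.nanargmin(mean))
    if cv_rule == "min":
        chosen = best
    elif cv_rule == "1se":
        ok = np.where(mean <= mean[best] + se[best])[0]
        chosen = int(ok.min())  # smallest C = strongest penalty
    else:
        raise ValueError(f"unknown cv_rule {cv_rule!r}")

    final = _fit(c_grid[chosen], np.ones(n, dtype=bool), max_iter=8000, tol=1e-4)
    nonzero = np.abs(final.coef_[0]) > 1e-8
    selected = tuple(counts.index[keep][nonzero])
    return SelectionResult(selected, 1.0 / c_grid[chosen], mixing, cv_rule, seed, dropped)


# ---------------------------------------------------------------------------
# stage 2: negative-binomial testing
# ---------------------------------------------------------------------------

def _group_fitted_means(Y: np.ndarray, sizes: np.ndarray, treat: np.ndarray) -> np.ndarray:
    """Ratio-estimator fitted means per annotation per sample."""
    M = np.zeros_like(Y, dtype=float)
    for g in (0, 1):
        idx = treat == g
        M[:, idx] = (Y[:, idx].sum(axis=1) / sizes[idx].sum())[:, None] * sizes[idx][None, :]
    return M


def estimate_common_dispersion(
    counts: np.ndarray, treatment: np.ndarray, offsets: np.ndarray,
    bounds: tuple[float, float] = (1e-4, 10.0),
) -> float:
    """Common NB dispersion by Cox-Reid adjusted profile likelihood.

    Maximizes the NB log likelihood summed over annotations at their
    group-wise fitted means, penalized by the Cox-Reid term
    ``0.5 * log det(X'WX)`` that corrects the bias from estimating two
    mean parameters per annotation from few samples.  Annotations with a
    zero group are excluded.  Shallow designs cannot support per-gene
    likelihoods, so strength is borrowed across the whole table.
    """
    sizes = np.exp(offsets)
    M = _group_fitted_means(np.asarray(counts, dtype=float), sizes, treatment)
    ok = (M > 0).all(axis=1)
    if not ok.any():
        raise ValueError("no annotation with positive counts in both groups")
    y = np.asarray(counts, dtype=float)[ok]
    m = M[ok]
    g0, g1 = treatment == 0, treatment == 1

    def neg_apl(logphi: float) -> float:
        phi = np.exp(logphi)
        r = 1.0 / phi
        ll = (
            special.gammaln(y + r) - special.gammaln(r) - special.gammaln(y + 1)
            + r * np.log(r / (r + m)) + y * np.log(np.where(y > 0, m / (r + m), 1.0))
        ).sum(axis=1)
        w = m / (1.0 + phi * m)
        cr = 0.5 * (np.log(w[:, g0].sum(axis=1)) + np.log(w[:, g1].sum(axis=1)))
        return -(ll - cr).sum()

    res = optimize.minimize_scalar(
        neg_apl, bounds=(np.log(bounds[0]), np.log(bounds[1])), method="bounded")
    return float(np.exp(res.x))


def moments_dispersion(y: np.ndarray, sizes: np.ndarray, treat: np.ndarray) -> float:
    """Per-annotation method-of-moments dispersion with leverage correction."""
    y = np.asarray(y, dtype=float)
    m = _group_fitted_means(y[None, :], sizes, treat)[0]
    n = y.size
    c = n / max(n - 2, 1)  # two fitted group means
    den = (m ** 2).sum()
    if den <= 0:
        return DISPERSION_FLOOR
    return max((c * (y - m) ** 2 - m).sum() / den, DISPERSION_FLOOR)


@dataclass(frozen=True)
class NBTestResult:
    coefficient: float   # log fold change (natural log), drought vs watered
    se: float
    p: float
    dispersion: float
    converged: bool


def nb_test(
    counts_for_annotation,
    treatment_labels,
    offsets,
    dispersion_mode: float | str = "moments",
) -> NBTestResult:
    """NB GLM Wald test of the treatment effect for one annotation.

    Fits ``log mu = b0 + b1 * treatment + offset`` with NB variance
    ``mu + phi * mu^2``.  ``dispersion_mode`` is either a known/shared
    ``phi`` (float; the Wald statistic is then referred to the normal) or
    ``"moments"`` (per-annotation leverage-corrected moment estimate; the
    statistic is referred to Student t with n-2 degrees of freedom to
    account for the dispersion being estimated from the same few
    samples).  Non-convergence or a zero group yields a flagged result
    with p = 1 rather than an exception.
    """
    y = np.asarray(counts_for_annotation, dtype=float)
    treat = _treatment_vector(treatment_labels)
    offsets = np.asarray(offsets, dtype=float)
    if not np.isfinite(offsets).all():
        raise ValueError("offsets must be finite (log scale)")
    sizes = np.exp(offsets)

    if y[treat == 0].sum() == 0 or y[treat == 1].sum() == 0:
        warnings.warn("a treatment group has all-zero counts; returning p=1",
                      stacklevel=2)
        return NBTestResult(np.nan, np.nan, 1.0, np.nan, False)

    if isinstance(dispersion_mode, str):
        if dispersion_mode != "moments":
            raise ValueError(f"unknown dispersion_mode {dispersion_mode!r}")
        phi = moments_dispersion(y, sizes, treat)
        df = y.size - 2
        use_t = True
    else:
        phi = max(float(dispersion_mode), DISPERSION_FLOOR)
        df = None
        use_t = False

    X = sm.add_constant(treat.astype(float))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(
                y, X, family=sm.families.NegativeBinomial(alpha=phi), offset=offsets
            ).fit(maxiter=100)
        coef = float(fit.params[1])
        se = float(fit.bse[1])
        if not np.isfinite(coef) or not np.isfinite(se) or se == 0:
            raise ValueError("degenerate fit")
    except Exception:
        warnings.warn("NB GLM failed to converge; returning p=1", stacklevel=2)
        return NBTestResult(np.nan, np.nan, 1.0, phi, False)

    z = coef / se
    if use_t:
        p = 2.0 * stats.t.sf(abs(z), df)
    else:
        p = 2.0 * stats.norm.sf(abs(z))
    return NBTestResult(coef, se, float(min(p, 1.0)), phi, True)


# ---------------------------------------------------------------------------
# full two-stage run
# ---------------------------------------------------------------------------

@dataclass
class DifferentialResult:
    """Per-annotation output of one two-stage run, with full provenance.

    ``frame`` is indexed by annotation ID with columns ``selected``,
    ``tested``, ``log_fc`` (natural-log drought-vs-watered coefficient),
    ``se``, ``p`` and ``significant``.
    """

    frame: pd.DataFrame
    method: int
    alpha: float
    seed: int
    normalization: NormalizationFactors
    selection: SelectionResult
    dispersion: float
    site: str
    n_imputed: int = 0

    @property
    def significant_ids(self) -> set[str]:
        return set(self.frame.index[self.frame["significant"]])

    def significant_at(self, alpha: float) -> set[str]:
        """Significant set at a different threshold (same fits re-thresholded)."""
        tested = self.frame["tested"] & self.frame["p"].notna()
        return set(self.frame.index[tested & (self.frame["p"] < alpha)])

    def to_tsv(self, path) -> None:
        out = self.frame.copy()
        out.index.name = "annotation_id"
        out.to_csv(path, sep="\t")


def run_ennb(
    table: CountTable,
    method: int = 1,
    alpha: float = 0.001,
    seed: int = 0,
    mixing: float = DEFAULT_MIXING,
    cv_rule: str = "1se",
    dispersion_mode: str = "common",
    min_nonzero: int | None = None,
    impute: bool = True,
    bh_correct: bool = False,
) -> DifferentialResult:
    """Run the full two-stage differential-abundance analysis on one site.

    The table must already be contaminant-filtered and contain a single
    field site.  Two-sample treatment groups are augmented with one
    imputed pseudo-replicate.  Stage 1 screens annotations with the
    elastic net; stage 2 fits NB GLMs to the screened annotations that
    additionally pass the prevalence filter (``min_nonzero`` nonzero
    samples; default all samples - shallow designs cannot support NB
    inference on annotations with structural zeros).  ``dispersion_mode``
    is ``"common"`` (shared dispersion by Cox-Reid profile likelihood;
    default) or ``"moments"`` (per-annotation).  Significance is
    ``p < alpha``, optionally Benjamini-Hochberg adjusted first.
    """
    if method not in (1, 2):
        raise ValueError("method must be 1 (TMM) or 2 (DESeq-type)")
    controls = table.control_samples()
    if controls:
        raise ValueError(
            f"table still contains control samples {controls}; "
            "run filter_contaminants first")
    sites = set(table.samples.loc[table.sample_ids, "site"])
    if len(sites) != 1:
        raise ValueError(
            f"run_ennb analyses one field site at a time, got {sorted(sites)}")
    site = sites.pop()

    # impute a third replicate for 2-sample cells
    n_imputed = 0
    if impute:
        treat = table.samples.loc[table.sample_ids, "treatment"]
        cells = {level: [s for s in table.sample_ids if treat[s] == level]
                 for level in sorted(treat.unique())}
        for level, cell in cells.items():
            if len(cell) == 2:
                aug = impute_replicate(table.select_samples(cell), seed=seed + 17)
                extra = aug.counts.columns[-1]
                counts = table.counts.copy()
                counts[extra] = aug.counts[extra]
                samples = pd.concat([table.samples, aug.samples.loc[[extra]]])
                table = CountTable(counts, samples)
                n_imputed += 1

    table, _ = drop_zero_rows(table)
    treatment = table.samples.loc[table.sample_ids, "treatment"]

    norm = tmm_factors(table) if method == 1 else deseq_size_factors(table)
    totals = table.sample_totals()
    if method == 1:
        eff = totals * norm.factors[totals.index]
    else:
        eff = norm.factors[totals.index]
    rel = eff / np.exp(np.mean(np.log(eff)))
    offsets = np.log(rel.to_numpy(dtype=float))

    selection = elastic_net_select(
        table.counts, treatment, mixing=mixing, seed=seed,
        cv_rule=cv_rule, rel_factors=rel)

    arr = table.counts.to_numpy(dtype=float)
    n_samples = arr.shape[1]
    if min_nonzero is None:
        min_nonzero = n_samples
    testable = (arr > 0).sum(axis=1) >= min_nonzero
    treat_vec = _treatment_vector(treatment)

    if dispersion_mode == "common":
        disp = estimate_common_dispersion(arr[testable], treat_vec, offsets)
        per_gene_mode: float | str = disp
    elif dispersion_mode == "moments":
        disp = float("nan")
        per_gene_mode = "moments"
    else:
        raise ValueError(f"unknown dispersion_mode {dispersion_mode!r}")

    frame = pd.DataFrame(
        {
            "selected": False, "tested": False,
            "log_fc": np.nan, "se": np.nan, "p": np.nan, "significant": False,
        },
        index=table.counts.index.copy(),
    )
    frame.loc[list(selection.selected), "selected"] = True
    to_test = frame.index[frame["selected"] & pd.Series(testable, index=frame.index)]
    for aid in to_test:
        res = nb_test(table.counts.loc[aid].to_numpy(), treatment, offsets, per_gene_mode)
        frame.loc[aid, ["tested", "log_fc", "se", "p"]] = True, res.coefficient, res.se, res.p

    pvals = frame.loc[frame["tested"], "p"]
    if bh_correct and len(pvals):
        adj = sm.stats.multipletests(pvals.to_numpy(), method="fdr_bh")[1]
        frame.loc[frame["tested"], "p"] = adj
    frame["significant"] = frame["tested"] & (frame["p"] < alpha)

    return DifferentialResult(
        frame=frame, method=method, alpha=alpha, seed=seed,
        normalization=norm, selection=selection, dispersion=disp,
        site=site, n_imputed=n_imputed)
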