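"""LC-MS feature-table post-processing and group statistics.

The processing chain mirrors standard targeted-MS practice for
metabolomics/lipidomics panels quantified by multiple-reaction-monitoring
(MRM) transitions:

1. :func:`select_mrm` — one quantifying MRM per analyte (highest
   signal-to-noise).
2. :func:`filter_missing` — drop features missing in more than 50% of
   samples.
3. :func:`impute_min` — replace remaining missing values with the lowest
   registered signal in the table (detection-limit imputation).
4. :func:`filter_qc_cv` — drop features whose coefficient of variation
   across repeated QC injections exceeds 30%.
5. :func:`total_sum_normalize` — divide each sample by its summed signal.

Statistics on the normalized table: per-feature log2 fold change between
groups, per-feature two-sided tests (Student's t by default; Welch and
Mann-Whitney available), Benjamini-Hochberg FDR adjustment, and z-score
matrices for heatmaps.

Missing values are encoded as NaN; zeros are observed values, not
missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as spstats
from statsmodels.stats.multitest import multipletests

from .errors import DataQualityError, ParameterError

#: Canonical order of the filtering chain (recorded per run).
PIPELINE_ORDER = (
    "select_mrm",
    "filter_missing",
    "impute_min",
    "filter_qc_cv",
    "total_sum_normalize",
)


@dataclass
class FeatureTable:
    """Samples x features signal matrix with sample and feature metadata.

    ``signal``: DataFrame, rows = samples, columns = features, NaN =
    missing. ``sample_meta``: indexed by sample id, columns ``group`` and
    ``is_qc``. ``feature_meta``: indexed by feature id, columns
    ``analyte_id`` (features sharing an analyte are alternative MRMs) and
    ``class`` (metabolite | lipid | neurotransmitter). ``log`` records
    each processing step applied, in order.
    """

    signal: pd.DataFrame
    sample_meta: pd.DataFrame
    feature_meta: pd.DataFrame
    log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.signal.to_numpy() < 0).any():
            raise ParameterError("feature table contains negative signals")
        if not self.signal.index.equals(self.sample_meta.index):
            raise ParameterError("signal rows do not match sample_meta index")
        if not self.signal.columns.equals(self.feature_meta.index):
            raise ParameterError("signal columns do not match feature_meta index")
        for col in ("group", "is_qc"):
            if col not in self.sample_meta.columns:
                raise ParameterError(f"sample_meta lacks required column {col!r}")
        if "analyte_id" not in self.feature_meta.columns:
            raise ParameterError("feature_meta lacks required column 'analyte_id'")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def n_features(self) -> int:
        return self.signal.shape[1]

    def study_samples(self) -> pd.Index:
        return self.sample_meta.index[~self.sample_meta["is_qc"].astype(bool)]

    def qc_samples(self) -> pd.Index:
        return self.sample_meta.index[self.sample_meta["is_qc"].astype(bool)]

    def _with(self, signal: pd.DataFrame, entry: dict) -> "FeatureTable":
        return FeatureTable(
            signal=signal,
            sample_meta=self.sample_meta,
            feature_meta=self.feature_meta.loc[signal.columns],
            log=self.log + [entry],
        )


def _qc_cv(signal: pd.DataFrame, qc_idx: pd.Index) -> pd.Series:
    qc = signal.loc[qc_idx]
    return qc.std(ddof=1) / qc.mean()


def select_mrm(t: FeatureTable) -> FeatureTable:
    """Keep one quantifying MRM per analyte.

    The quality score is mean study-sample signal divided by the SD of
    the feature across QC injections (mean signal alone when there are no
    QC samples). Exact ties keep the first-listed MRM; ties are logged.
    """
    mean_sig = t.signal.loc[t.study_samples()].mean()
    qc_idx = t.qc_samples()
    if len(qc_idx) >= 2:
        qc_sd = t.signal.loc[qc_idx].std(ddof=1)
        score = mean_sig / qc_sd.replace(0.0, np.nan)
        score = score.fillna(np.inf).where(mean_sig.notna(), np.nan)
    else:
        score = mean_sig

    keep: list[str] = []
    ties: list[str] = []
    for analyte, members in t.feature_meta.groupby("analyte_id", sort=False).groups.items():
        members = list(members)
        if len(members) == 1:
            keep.append(members[0])
            continue
        s = score[members]
        best = s.max()
        winners = [f for f in members if s[f] == best]
        if len(winners) > 1:
            ties.append(str(analyte))
        keep.append(winners[0])
    keep_in_order = [f for f in t.signal.columns if f in set(keep)]
    entry = {
        "step": "select_mrm",
        "n_in": t.n_features,
        "n_out": len(keep_in_order),
        "ties": ties,
    }
    return t._with(t.signal[keep_in_order], entry)


def filter_missing(t: FeatureTable, max_frac: float = 0.5) -> FeatureTable:
    """Discard features missing in strictly more than ``max_frac`` of samples.

    The fraction is computed over study (non-QC) samples; QC injections
    are policed separately by the CV filter.
    """
    frac = t.signal.loc[t.study_samples()].isna().mean()
    keep = frac.index[frac <= max_frac]
    removed = [f for f in t.signal.columns if f not in set(keep)]
    entry = {
        "step": "filter_missing",
        "max_frac": max_frac,
        "n_in": t.n_features,
        "n_out": len(keep),
        "removed": removed,
    }
    return t._with(t.signal[keep], entry)


def impute_min(t: FeatureTable, per_feature: bool = False) -> FeatureTable:
    """Replace remaining missing values with the lowest registered signal.

    The default minimum is global over the whole filtered table;
    ``per_feature=True`` uses each feature's own minimum instead.
    """
    sig = t.signal.copy()
    n_missing = int(sig.isna().to_numpy().sum())
    if sig.notna().to_numpy().sum() == 0:
        raise DataQualityError("cannot impute: table contains no observed values")
    if per_feature:
        sig = sig.fillna(sig.min())
        if sig.isna().to_numpy().any():
            raise DataQualityError(
                "per-feature imputation failed: some feature has no observed value"
            )
    else:
        sig = sig.fillna(float(np.nanmin(sig.to_numpy())))
    entry = {"step": "impute_min", "n_imputed": n_missing, "per_feature": per_feature}
    return t._with(sig, entry)


def filter_qc_cv(t: FeatureTable, max_cv: float = 0.3) -> FeatureTable:
    """Discard features whose QC coefficient of variation exceeds ``max_cv``.

    CV = sample SD / mean over the QC-flagged injections; at least two QC
    samples are required for the CV to be defined.
    """
    qc_idx = t.qc_samples()
    if len(qc_idx) < 2:
        raise DataQualityError(
            f"QC CV requires >= 2 QC samples, found {len(qc_idx)}"
        )
    cv = _qc_cv(t.signal, qc_idx)
    keep = cv.index[cv <= max_cv]
    removed = [f for f in t.signal.columns if f not in set(keep)]
    entry = {
        "step": "filter_qc_cv",
        "max_cv": max_cv,
        "n_in": t.n_features,
        "n_out": len(keep),
        "removed": removed,
    }
    return t._with(t.signal[keep], entry)


def total_sum_normalize(t: FeatureTable) -> FeatureTable:
    """Divide each sample's signals by that sample's total (rows sum to 1)."""
    if t.signal.isna().to_numpy().any():
        raise ParameterError("normalize after imputation: table still has missing values")
    totals = t.signal.sum(axis=1)
    bad = totals.index[totals <= 0]
    if len(bad) > 0:
        raise DataQualityError(f"zero-total sample(s): {list(bad)}")
    entry = {"step": "total_sum_normalize"}
    return t._with(t.signal.div(totals, axis=0), entry)


def run_lcms_pipeline(
    t: FeatureTable,
    max_missing: float = 0.5,
    max_cv: float = 0.3,
    per_feature_imputation: bool = False,
) -> FeatureTable:
    """Run the full chain in canonical order (see :data:`PIPELINE_ORDER`).

    The MRM selection runs first so missingness fractions are computed on
    the quantifying MRM only; the returned table's ``log`` records the
    executed order and per-step removal counts.
    """
    t = select_mrm(t)
    t = filter_missing(t, max_frac=max_missing)
    t = impute_min(t, per_feature=per_feature_imputation)
    t = filter_qc_cv(t, max_cv=max_cv)
    return total_sum_normalize(t)


# --------------------------------------------------------------------------
# Statistics
# --------------------------------------------------------------------------


def bh_adjust(pvals: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1).

    NaN entries are excluded from the adjustment and returned as NaN.
    """
    arr = np.asarray(pvals, dtype=float)
    out = np.full(arr.shape, np.nan)
    ok = ~np.isnan(arr)
    if np.any((arr[ok] < 0) | (arr[ok] > 1)):
        raise ParameterError("p-values must lie in [0, 1]")
    if ok.sum() > 0:
        out[ok] = multipletests(arr[ok], method="fdr_bh")[1]
    return out


@dataclass
class DifferentialResult:
    """Per-feature group-comparison statistics.

    ``table`` columns: ``log2fc`` (log2 of group-b mean over group-a
    mean), ``p``, ``q`` (BH-adjusted), ``neglog10p``, ``undefined_fc``
    (True where a zero group mean made the fold change undefined).
    """

    table: pd.DataFrame
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    test: str
    bh_scope: str


def differential(
    t: FeatureTable,
    group_a: str,
    group_b: str,
    test: str = "student",
    bh_scope: str = "class",
) -> DifferentialResult:
    """Two-group differential statistics on a normalized table.

    ``log2fc = log2(mean_b / mean_a)`` with group b (the mutant line) in
    the numerator. ``test`` is ``student`` (equal-variance t), ``welch``
    or ``mannwhitney``; p-values are two-sided. BH adjustment runs within
    each feature class by default (``bh_scope="class"``) or across the
    whole panel (``"global"``).
    """
    if test not in ("student", "welch", "mannwhitney"):
        raise ParameterError(f"unknown test {test!r}")
    if bh_scope not in ("class", "global"):
        raise ParameterError("bh_scope must be 'class' or 'global'")
    meta = t.sample_meta
    idx_a = meta.index[(meta["group"] == group_a) & ~meta["is_qc"].astype(bool)]
    idx_b = meta.index[(meta["group"] == group_b) & ~meta["is_qc"].astype(bool)]
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise DataQualityError(
            f"both groups need >= 2 samples (got {len(idx_a)} {group_a!r}, "
            f"{len(idx_b)} {group_b!r})"
        )
    a = t.signal.loc[idx_a].to_numpy()
    b = t.signal.loc[idx_b].to_numpy()
    mean_a, mean_b = a.mean(axis=0), b.mean(axis=0)

    undefined = (mean_a <= 0) | (mean_b <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.where(undefined, np.nan, np.log2(mean_b / mean_a))

    if test == "mannwhitney":
        p = np.array(
            [
                spstats.mannwhitneyu(b[:, j], a[:, j], alternative="two-sided").pvalue
                for j in range(a.shape[1])
            ]
        )
    else:
        p = spstats.ttest_ind(b, a, axis=0, equal_var=(test == "student")).pvalue
    p = np.asarray(p, dtype=float)

    res = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": p,
            "undefined_fc": undefined,
        },
        index=t.signal.columns,
    )
    res["q"] = np.nan
    if bh_scope == "class" and "class" in t.feature_meta.columns:
        for _, members in t.feature_meta.groupby("class").groups.items():
            members = res.index.intersection(members)
            res.loc[members, "q"] = bh_adjust(res.loc[members, "p"])
    else:
        res["q"] = bh_adjust(res["p"])
    with np.errstate(divide="ignore"):
        res["neglog10p"] = -np.log10(res["p"])
    return DifferentialResult(
        table=res,
        group_a=group_a,
        group_b=group_b,
        n_a=len(idx_a),
        n_b=len(idx_b),
        test=test,
        bh_scope=bh_scope,
    )


@dataclass
class HeatmapMatrix:
    """Feature x sample z-scores plus the list of zero-SD features."""

    z: pd.DataFrame
    constant_features: list[str]


def zscore_matrix(t: FeatureTable, include_qc: bool = False) -> HeatmapMatrix:
    """Centre and scale each feature across samples (rows: mean 0, SD 1).

    Zero-SD features are emitted as all-zero rows and flagged. QC
    injections are excluded unless ``include_qc``.
    """
    idx = t.signal.index if include_qc else t.study_samples()
    x = t.signal.loc[idx].T  # features x samples
    mean = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    constant = sd.index[sd == 0].tolist()
    safe_sd = sd.replace(0.0, np.nan)
    z = x.sub(mean, axis=0).div(safe_sd, axis=0)
    z.loc[constant] = 0.0
    return HeatmapMatrix(z=z, constant_features=constant)
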