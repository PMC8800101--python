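"""Panel RT-qPCR differential-expression pipeline.

Implements the selection chain used for miRNome panels:

1. detection filter — assays with Cq above a cutoff (or undetected) in at
   least half the samples are considered not expressed;
2. global-mean normalization — per-sample ΔCq against the mean Cq of a
   reference set of reliably detected assays (a robust alternative to a
   single housekeeping gene when hundreds of assays are measured);
3. fold-changes by the 2^-ΔΔCq method against the control-group mean;
4. a control-variability filter excluding assays whose fold-change exceeds
   2 (or falls below 0.5) in any single control sample;
5. per-assay two-sample t-tests on ΔCq (no multiple-testing correction,
   matching the historical analysis; BH q-values are emitted for
   information only);
6. Ward.D2 hierarchical clustering of samples on the differential subset;
7. hypergeometric enrichment of a genomic locus cluster in the
   differential set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .panel_io import CqPanel, MirnaAnnotation, PanelValidationError

logger = logging.getLogger(__name__)

DEFAULT_CQ_MAX = 35.0
DEFAULT_UNDETECTED_FRAC = 0.5
DEFAULT_ALPHA = 0.05


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class DeltaCqMatrix:
    """Per-sample global-mean normalized expression.

    ``delta_cq[i, s] = cq[i, s] - mean over reference_set of cq[., s]``, so
    within each sample the mean ΔCq over the reference set is exactly zero.
    Lower ΔCq means higher relative expression.
    """

    delta_cq: pd.DataFrame
    reference_set: list[str]
    groups: pd.Series

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.delta_cq.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.delta_cq.columns)

    @property
    def case_ids(self) -> list[str]:
        return list(self.groups.index[self.groups == "case"])

    @property
    def control_ids(self) -> list[str]:
        return list(self.groups.index[self.groups == "control"])


@dataclass
class LinkageTree:
    """Result of agglomerative clustering of samples.

    ``linkage`` is in scipy linkage form (merge pairs, height, size);
    Ward.D2 heights are non-decreasing along the merge sequence.
    """

    linkage: np.ndarray
    sample_ids: list[str]
    leaf_order: list[str]
    two_cluster_labels: pd.Series

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


@dataclass
class EnrichmentResult:
    """Upper-tail hypergeometric test of locus-cluster membership.

    Of ``N`` assays in the universe, ``K`` belong to the cluster; a
    differential subset of size ``n`` contains ``k`` members.  ``p_value``
    is P(X >= k) for X ~ Hypergeom(N, K, n).
    """

    cluster_id: str
    k: int
    n: int
    K: int
    N: int
    p_value: float


# ---------------------------------------------------------------------------
# 1. detection filter
# ---------------------------------------------------------------------------

def filter_expressed(
    panel: CqPanel,
    cq_max: float = DEFAULT_CQ_MAX,
    undetected_frac: float = DEFAULT_UNDETECTED_FRAC,
) -> tuple[CqPanel, pd.DataFrame]:
    """Drop assays not reliably expressed.

    An assay is excluded when the fraction of samples with Cq > ``cq_max``
    (undetected cells count as above the cutoff) is at least
    ``undetected_frac``.  Returns the retained panel and a per-assay report.
    """
    if cq_max <= 0:
        raise ValueError(f"cq_max must be positive, got {cq_max}")
    if not 0 < undetected_frac <= 1:
        raise ValueError(f"undetected_frac must be in (0, 1], got {undetected_frac}")
    vals = panel.cq.to_numpy(float)
    above = np.isnan(vals) | (vals > cq_max)
    n_samples = vals.shape[1]
    frac = above.sum(axis=1) / n_samples
    retained_mask = frac < undetected_frac
    report = pd.DataFrame(
        {
            "n_above_cutoff": above.sum(axis=1),
            "n_samples": n_samples,
            "frac_above_cutoff": frac,
            "retained": retained_mask,
        },
        index=panel.cq.index,
    )
    report.index.name = "mirna"
    retained = panel.subset(panel.cq.index[retained_mask])
    logger.info(
        "detection filter: retained %d / %d assays (Cq cutoff %.3g, fraction %.3g)",
        retained_mask.sum(), len(retained_mask), cq_max, undetected_frac,
    )
    return retained, report


# ---------------------------------------------------------------------------
# 2. global-mean normalization
# ---------------------------------------------------------------------------

def global_mean_normalize(
    panel: CqPanel,
    reference_rule: str | Iterable[str] = "all_samples_detected",
    cq_max: float = DEFAULT_CQ_MAX,
) -> DeltaCqMatrix:
    """Normalize a retained panel to per-sample global-mean ΔCq.

    ``reference_rule``:

    * ``"all_samples_detected"`` (default) — assays with Cq <= ``cq_max`` in
      every sample form the reference set;
    * ``"retained"`` — all assays in the panel;
    * an explicit iterable of miRNA ids.

    Undetected cells outside the reference set propagate as missing ΔCq.
    """
    vals = panel.cq.to_numpy(float)
    if isinstance(reference_rule, str):
        if reference_rule == "all_samples_detected":
            ref_mask = (~np.isnan(vals) & (vals <= cq_max)).all(axis=1)
            ref_ids = list(panel.cq.index[ref_mask])
        elif reference_rule == "retained":
            ref_ids = list(panel.cq.index)
        else:
            raise ValueError(f"unknown reference_rule {reference_rule!r}")
    else:
        ref_ids = list(reference_rule)
        missing = set(ref_ids) - set(panel.cq.index)
        if missing:
            raise PanelValidationError(
                f"reference ids not in panel: {sorted(missing)}"
            )
    if not ref_ids:
        raise PanelValidationError("empty reference set for global-mean normalization")
    ref = panel.cq.loc[ref_ids]
    if ref.isna().to_numpy().any():
        # cannot happen under all_samples_detected; explicit sets may violate it
        raise PanelValidationError("undetected Cq inside the reference set")
    global_mean = ref.mean(axis=0)
    delta = panel.cq.sub(global_mean, axis=1)
    return DeltaCqMatrix(delta, ref_ids, panel.groups.copy())


# ---------------------------------------------------------------------------
# 3. fold-change (2^-ΔΔCq)
# ---------------------------------------------------------------------------

def fold_change(
    delta: DeltaCqMatrix,
    case_ids: Sequence[str],
    control_ids: Sequence[str],
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-sample fold-changes and the case-group mean fold-change.

    ΔΔCq[i, s] = ΔCq[i, s] - mean over controls of ΔCq[i, .];
    FC[i, s] = 2^-ΔΔCq[i, s].  The reported ``mean_fc_case`` is the
    arithmetic mean of per-sample FCs over case samples.  Assays with a
    missing ΔCq in any involved sample are skipped (logged) and carry NaN.
    """
    case_ids, control_ids = _check_groups(delta, case_ids, control_ids)
    sub = delta.delta_cq[list(case_ids) + list(control_ids)]
    ctrl_mean = delta.delta_cq[control_ids].mean(axis=1, skipna=False)
    ddcq = sub.sub(ctrl_mean, axis=0)
    fc = np.power(2.0, -ddcq)
    complete = sub.notna().all(axis=1)
    skipped = list(sub.index[~complete])
    if skipped:
        logger.info("fold_change: skipped %d assays with missing ΔCq", len(skipped))
        fc.loc[skipped] = np.nan
    mean_fc_case = fc[list(case_ids)].mean(axis=1)
    mean_fc_case.name = "mean_fc_case"
    return fc, mean_fc_case


def _check_groups(delta, case_ids, control_ids):
    case_ids = list(case_ids) if case_ids is not None else delta.case_ids
    control_ids = list(control_ids) if control_ids is not None else delta.control_ids
    if not case_ids or not control_ids:
        raise PanelValidationError("both case and control sample sets must be non-empty")
    if set(case_ids) & set(control_ids):
        raise PanelValidationError("case and control sample sets overlap")
    missing = (set(case_ids) | set(control_ids)) - set(delta.sample_ids)
    if missing:
        raise PanelValidationError(f"sample ids not in matrix: {sorted(missing)}")
    return case_ids, control_ids


# ---------------------------------------------------------------------------
# 4. control-variability filter
# ---------------------------------------------------------------------------

def control_variability_filter(
    delta: DeltaCqMatrix,
    control_ids: Sequence[str] | None = None,
    fc_hi: float = 2.0,
    fc_lo: float = 0.5,
) -> tuple[set[str], pd.DataFrame]:
    """Exclude assays too variable within the control group.

    For each control sample c, FC[i, c] = 2^-(ΔCq[i, c] - control mean).
    An assay is excluded when any control FC exceeds ``fc_hi`` or falls
    below ``fc_lo``.  Returns the excluded id set and the control FC table.
    """
    if fc_lo >= fc_hi:
        raise ValueError(f"fc_lo must be < fc_hi, got {fc_lo} >= {fc_hi}")
    control_ids = list(control_ids) if control_ids is not None else delta.control_ids
    if not control_ids:
        raise PanelValidationError("control sample set must be non-empty")
    ctrl = delta.delta_cq[control_ids]
    ddcq = ctrl.sub(ctrl.mean(axis=1), axis=0)
    fc = np.power(2.0, -ddcq)
    excluded_mask = ((fc > fc_hi) | (fc < fc_lo)).any(axis=1)
    excluded = set(fc.index[excluded_mask])
    if excluded:
        logger.info("control-variability filter: excluded %d assays", len(excluded))
    return excluded, fc


# ---------------------------------------------------------------------------
# 5. differential test
# ---------------------------------------------------------------------------

def differential_test(
    delta: DeltaCqMatrix,
    case_ids: Sequence[str] | None = None,
    control_ids: Sequence[str] | None = None,
    alpha: float = DEFAULT_ALPHA,
    variant: str = "student",
    fc_hi: float = 2.0,
    fc_lo: float = 0.5,
    apply_control_filter: bool = True,
) -> pd.DataFrame:
    """Per-assay two-sample t-test on ΔCq, with fold-changes and filters.

    Returns a DE table indexed by miRNA with columns:

    * ``mean_fc_case`` — arithmetic mean of case-sample 2^-ΔΔCq;
    * ``geom_fc_case`` — 2^-(mean case ΔΔCq), emitted alongside;
    * ``p_value`` — two-sided t-test p (``variant``: "student" pooled
      variance, or "welch");
    * ``q_value`` — Benjamini-Hochberg adjusted p, informational only;
    * ``direction`` — "up" iff mean_fc_case > 1 else "down";
    * ``significant`` — p < alpha;
    * ``excluded_by_control_filter`` — control-variability flag;
    * ``in_de_list`` — significant and not excluded (the final DE set).

    Zero-variance conventions (logged): both groups constant with equal
    means -> p = 1; constant with unequal means -> p = 0.
    """
    if variant not in ("student", "welch"):
        raise ValueError(f"variant must be 'student' or 'welch', got {variant!r}")
    case_ids, control_ids = _check_groups(delta, case_ids, control_ids)
    case = delta.delta_cq[case_ids].to_numpy(float)
    ctrl = delta.delta_cq[control_ids].to_numpy(float)
    if case.shape[1] < 2 or ctrl.shape[1] < 2:
        raise PanelValidationError("need >= 2 samples per group for a t-test")

    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # near-constant rows trip scipy's precision-loss warning; the
        # zero-variance conventions below handle those rows explicitly
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(
            case, ctrl, axis=1, equal_var=(variant == "student"), nan_policy="omit"
        )
        p = np.asarray(res.pvalue, float)

    # zero-variance conventions
    case_sd = np.nanstd(case, axis=1)
    ctrl_sd = np.nanstd(ctrl, axis=1)
    both_const = (case_sd == 0) & (ctrl_sd == 0)
    mean_diff = np.nanmean(case, axis=1) - np.nanmean(ctrl, axis=1)
    degenerate = both_const & np.isfinite(mean_diff)
    if degenerate.any():
        p[degenerate & (mean_diff == 0)] = 1.0
        p[degenerate & (mean_diff != 0)] = 0.0
        logger.info(
            "differential_test: %d assays with zero variance in both groups "
            "(p set by convention)", int(degenerate.sum()),
        )

    fc, mean_fc = fold_change(delta, case_ids, control_ids)
    ctrl_mean = delta.delta_cq[control_ids].mean(axis=1, skipna=False)
    case_mean_ddcq = delta.delta_cq[case_ids].mean(axis=1, skipna=False) - ctrl_mean
    geom_fc = np.power(2.0, -case_mean_ddcq)

    finite = np.isfinite(p)
    q = np.full_like(p, np.nan)
    if finite.any():
        q[finite] = multipletests(p[finite], method="fdr_bh")[1]

    if apply_control_filter:
        excluded, _ = control_variability_filter(delta, control_ids, fc_hi, fc_lo)
    else:
        excluded = set()
    table = pd.DataFrame(
        {
            "mean_fc_case": mean_fc,
            "geom_fc_case": geom_fc,
            "p_value": p,
            "q_value": q,
            "direction": np.where(mean_fc > 1, "up", "down"),
            "significant": (p < alpha) & np.isfinite(p),
            "excluded_by_control_filter": [m in excluded for m in delta.mirna_ids],
        },
        index=delta.delta_cq.index,
    )
    table.index.name = "mirna"
    table["in_de_list"] = table["significant"] & ~table["excluded_by_control_filter"]
    return table


# ---------------------------------------------------------------------------
# 6. sample clustering (Ward.D2 on Euclidean distances)
# ---------------------------------------------------------------------------

def cluster_samples(delta_subset: DeltaCqMatrix) -> LinkageTree:
    """Agglomerate samples by Ward.D2 on Euclidean sample-sample distances.

    Rows (assays) with any missing ΔCq are dropped (logged).  Cutting the
    tree at two clusters yields the group assignment reported alongside.
    """
    d = delta_subset.delta_cq
    complete = d.notna().all(axis=1)
    if (~complete).any():
        logger.info("cluster_samples: dropped %d assays with missing ΔCq",
                    int((~complete).sum()))
        d = d.loc[complete]
    samples = list(d.columns)
    if len(samples) < 2:
        raise PanelValidationError("clustering needs at least 2 samples")
    x = d.to_numpy(float).T  # samples x assays
    link = hierarchy.linkage(pdist(x, metric="euclidean"), method="ward")
    order = [samples[i] for i in hierarchy.leaves_list(link)]
    labels = hierarchy.fcluster(link, t=2, criterion="maxclust")
    return LinkageTree(
        linkage=link,
        sample_ids=samples,
        leaf_order=order,
        two_cluster_labels=pd.Series(labels, index=samples, name="cluster"),
    )


# ---------------------------------------------------------------------------
# 7. locus-cluster enrichment
# ---------------------------------------------------------------------------

def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n): the probability of drawing at
    least k cluster members in a size-n draw from a universe of N
    containing K members."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def cluster_enrichment(
    de_subset: Iterable[str],
    universe: Iterable[str],
    annotation: MirnaAnnotation,
    cluster_id: str,
) -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment of a locus cluster.

    The universe should be the expressed (retained) assays that carry an
    annotation; panel assays absent from the annotation are excluded from
    the universe by the caller and flagged in the report.
    """
    universe = set(universe)
    de = set(de_subset)
    if not de <= universe:
        raise PanelValidationError(
            f"DE subset not contained in universe: {sorted(de - universe)}"
        )
    members = annotation.cluster_members(cluster_id)
    N = len(universe)
    K = len(members & universe)
    n = len(de)
    k = len(members & de)
    if K == 0:
        logger.warning("cluster %r has no members in the universe; p = 1", cluster_id)
        return EnrichmentResult(cluster_id, k, n, K, N, 1.0)
    return EnrichmentResult(cluster_id, k, n, K, N, hypergeom_upper_tail(k, N, K, n))


# ---------------------------------------------------------------------------
# single-assay reference-gene quantification
# ---------------------------------------------------------------------------

def normalize_to_reference(
    panel: CqPanel,
    target_id: str,
    reference_id: str,
    case_ids: Sequence[str] | None = None,
    control_ids: Sequence[str] | None = None,
    undetected_cq: float | None = None,
) -> dict:
    """2^-ΔΔCq quantification of one assay against a reference gene.

    ΔCq = Cq_target - Cq_reference per sample; fold-changes are relative to
    the control-group mean ΔCq.  When ``undetected_cq`` is given (e.g. 41),
    undetected target cells are substituted with that Cq; otherwise they
    propagate as missing.  An undetected reference is always a hard error —
    the reference must amplify.
    """
    for mid in (target_id, reference_id):
        if mid not in panel.cq.index:
            raise KeyError(f"assay {mid!r} not in panel")
    case_ids = list(case_ids) if case_ids is not None else panel.case_ids
    control_ids = list(control_ids) if control_ids is not None else panel.control_ids
    if not control_ids:
        raise PanelValidationError("control sample set must be non-empty")
    samples = list(case_ids) + list(control_ids)
    target = panel.cq.loc[target_id, samples].astype(float)
    ref = panel.cq.loc[reference_id, samples].astype(float)
    if ref.isna().any():
        bad = list(ref.index[ref.isna()])
        raise PanelValidationError(
            f"reference assay {reference_id!r} undetected in sample(s) {bad}"
        )
    substituted = []
    if undetected_cq is not None and target.isna().any():
        substituted = list(target.index[target.isna()])
        target = target.fillna(float(undetected_cq))
    dcq = target - ref
    ctrl_mean = dcq[control_ids].mean()
    fc = np.power(2.0, -(dcq - ctrl_mean))
    return {
        "delta_cq": dcq,
        "fc": fc,
        "mean_fc_case": float(fc[case_ids].mean()) if case_ids else math.nan,
        "mean_fc_control": float(fc[control_ids].mean()),
        "substituted_samples": substituted,
    }


# ---------------------------------------------------------------------------
# pipeline composition
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    """Everything the panel pipeline produces, stage by stage."""

    params: dict
    filter_report: pd.DataFrame
    retained: CqPanel
    delta: DeltaCqMatrix
    de_table: pd.DataFrame
    linkage: LinkageTree | None
    enrichment: dict[str, EnrichmentResult] = field(default_factory=dict)
    unannotated: list[str] = field(default_factory=list)

    @property
    def de_ids(self) -> list[str]:
        return list(self.de_table.index[self.de_table["in_de_list"]])

    @property
    def up_ids(self) -> list[str]:
        t = self.de_table
        return list(t.index[t["in_de_list"] & (t["direction"] == "up")])

    @property
    def down_ids(self) -> list[str]:
        t = self.de_table
        return list(t.index[t["in_de_list"] & (t["direction"] == "down")])


def run_pipeline(
    panel: CqPanel,
    annotation: MirnaAnnotation | None = None,
    cluster_id: str | None = None,
    cq_max: float = DEFAULT_CQ_MAX,
    undetected_frac: float = DEFAULT_UNDETECTED_FRAC,
    reference_rule: str | Iterable[str] = "all_samples_detected",
    alpha: float = DEFAULT_ALPHA,
    variant: str = "student",
    fc_hi: float = 2.0,
    fc_lo: float = 0.5,
    cluster: bool = True,
) -> PipelineResult:
    """Run detection filter -> normalization -> t-test (with control-FC
    exclusion) -> clustering -> enrichment on a grouped panel."""
    panel.require_groups()
    retained, filt_report = filter_expressed(panel, cq_max, undetected_frac)
    delta = global_mean_normalize(retained, reference_rule, cq_max)
    de_table = differential_test(
        delta, alpha=alpha, variant=variant, fc_hi=fc_hi, fc_lo=fc_lo
    )
    result = PipelineResult(
        params={
            "cq_max": cq_max,
            "undetected_frac": undetected_frac,
            "reference_rule": reference_rule if isinstance(reference_rule, str)
            else sorted(reference_rule),
            "reference_set_size": len(delta.reference_set),
            "alpha": alpha,
            "variant": variant,
            "fc_hi": fc_hi,
            "fc_lo": fc_lo,
        },
        filter_report=filt_report,
        retained=retained,
        delta=delta,
        de_table=de_table,
        linkage=None,
    )
    de_ids = result.de_ids
    if cluster and de_ids and len(delta.sample_ids) >= 2:
        sub = DeltaCqMatrix(
            delta.delta_cq.loc[de_ids], delta.reference_set, delta.groups
        )
        result.linkage = cluster_samples(sub)
    if annotation is not None and cluster_id is not None:
        annotated = set(annotation.mirna_ids)
        universe = [m for m in retained.mirna_ids if m in annotated]
        result.unannotated = [m for m in retained.mirna_ids if m not in annotated]
        for name, subset in (
            ("up", [m for m in result.up_ids if m in annotated]),
            ("down", [m for m in result.down_ids if m in annotated]),
            ("combined", [m for m in de_ids if m in annotated]),
        ):
            result.enrichment[name] = cluster_enrichment(
                subset, universe, annotation, cluster_id
            )
    return result
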