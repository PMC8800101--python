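"""Simulators with known ground truth for both pipeline arms.

``generate_cq_panel`` emulates a panel RT-qPCR run: per-assay baseline Cq,
per-sample global shifts (removed exactly by global-mean normalization),
Gaussian technical noise, a coherent case-only expression effect confined to
one genomic cluster, and right-censoring at high Cq (values above the
censoring cutoff are emitted as detected-but-high; past the no-amplification
cutoff the cell becomes undetected).  Effects are planted on the cycle
(ΔCq) scale so the true fold-change is exactly 2^effect by construction.

``generate_nuclei`` emulates segmented two-channel 3D-FISH data: ellipsoidal
nuclei, a subtelomeric probe placed at a controlled radial fraction of the
envelope, and a cluster probe displaced from it by a controlled center
separation; optional anisotropic voxel quantization (0.1 x 0.1 x 0.24 μm)
mimics the microscope sampling grid.

``synthetic_reference_panel`` is a deterministic constructed fixture — a
synthetic stand-in for a deposited 375-assay x 15-sample panel — whose
selection-pipeline outcome (retained count, reference-set size, DE counts,
cluster enrichment, top fold-change) is known exactly by construction.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .panel_io import CqPanel, MirnaAnnotation
from .topology import (
    CLUSTER_CHANNEL,
    SUBTEL_CHANNEL,
    NucleusGeometry,
    ProbeSignal,
    ellipsoid_surface_point,
)

DEFAULT_VOXEL_UM = (0.1, 0.1, 0.24)


# ---------------------------------------------------------------------------
# Cq panel simulation
# ---------------------------------------------------------------------------

@dataclass
class PanelSimConfig:
    """Study-condition parameters for a simulated Cq panel.

    Defaults mirror the profiled design: 375 assays, 8 case vs 7 control
    samples, a 7-member locus cluster carrying a 1-cycle (2-fold) case
    effect, 0.5-cycle technical noise, censoring at Cq 35 and loss of
    amplification past Cq 40.
    """

    n_mirnas: int = 375
    n_case: int = 8
    n_control: int = 7
    cluster_size: int = 7
    effect_cycles: float = 1.0       # planted log2 fold-change, in ΔCq cycles
    baseline_range: tuple[float, float] = (20.0, 34.0)
    sample_shift_sd: float = 0.3     # per-sample global shift, cycles
    noise_sd: float = 0.5            # technical noise, cycles
    censor_cq: float = 35.0
    no_amp_cq: float = 40.0
    cluster_id: str = "14q32"

    def validate(self) -> None:
        if self.n_mirnas < 1 or self.n_case < 2 or self.n_control < 2:
            raise ValueError("need >= 1 assay and >= 2 samples per group")
        if self.cluster_size > self.n_mirnas:
            raise ValueError("cluster_size exceeds n_mirnas")
        if self.sample_shift_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.no_amp_cq < self.censor_cq:
            raise ValueError("no_amp_cq must be >= censor_cq")


@dataclass
class PanelTruth:
    """Ground truth accompanying a simulated panel."""

    planted_ids: list[str]
    true_log2_fc: dict[str, float]
    annotation: MirnaAnnotation
    config: PanelSimConfig


def _panel_annotation(mirna_ids: Sequence[str], cluster_ids: Sequence[str],
                      cluster_label: str) -> MirnaAnnotation:
    cluster_ids = set(cluster_ids)
    recs = []
    chrom_cycle = [f"chr{c}" for c in list(range(1, 14)) + list(range(15, 23))]
    j = 0
    for i, mid in enumerate(mirna_ids):
        if mid in cluster_ids:
            start = 100_834_432 + 1_000 * i
            recs.append(("chr14", start, start + 80, mid, "14q32.31", cluster_label))
        else:
            chrom = chrom_cycle[j % len(chrom_cycle)]
            start = 1_000_000 + 5_000 * i
            recs.append((chrom, start, start + 80, mid, ".", "."))
            j += 1
    return MirnaAnnotation(pd.DataFrame(recs, columns=MirnaAnnotation.COLUMNS))


def generate_cq_panel(
    config: PanelSimConfig | None = None, seed: int | None = 0
) -> tuple[CqPanel, PanelTruth]:
    """Simulate a grouped Cq panel with a planted cluster effect.

    Cq[i, s] = baseline_i + shift_s - effect * [s is case][i in cluster] + ε,
    ε ~ Normal(0, noise_sd²).  Values above ``no_amp_cq`` become undetected;
    values in (censor_cq, no_amp_cq] stay as detected-but-high.  The same
    seed reproduces the panel bit for bit.
    """
    config = config or PanelSimConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n_mirnas
    width = len(str(n))
    cluster_ids = [f"synmiR-{config.cluster_id}-{i + 1:02d}"
                   for i in range(config.cluster_size)]
    other_ids = [f"synmiR-{i + 1:0{width}d}"
                 for i in range(n - config.cluster_size)]
    mirna_ids = cluster_ids + other_ids
    samples = ([f"case-{i + 1:02d}" for i in range(config.n_case)]
               + [f"ctrl-{i + 1:02d}" for i in range(config.n_control)])
    groups = pd.Series(["case"] * config.n_case + ["control"] * config.n_control,
                       index=samples)

    baseline = rng.uniform(*config.baseline_range, size=n)
    shift = rng.normal(0.0, config.sample_shift_sd, size=len(samples))
    eps = rng.normal(0.0, config.noise_sd, size=(n, len(samples)))
    cq = baseline[:, None] + shift[None, :] + eps
    is_case = (groups == "case").to_numpy()
    cq[: config.cluster_size, is_case] -= config.effect_cycles
    cq[cq > config.no_amp_cq] = np.nan  # no amplification

    panel = CqPanel(
        pd.DataFrame(cq, index=mirna_ids, columns=samples),
        groups,
        pd.Series("", index=samples, dtype=object),
    )
    truth = PanelTruth(
        planted_ids=cluster_ids,
        true_log2_fc={m: config.effect_cycles for m in cluster_ids},
        annotation=_panel_annotation(mirna_ids, cluster_ids, config.cluster_id),
        config=config,
    )
    return panel, truth


# ---------------------------------------------------------------------------
# nuclei simulation
# ---------------------------------------------------------------------------

@dataclass
class NucleusSimConfig:
    """Study-condition parameters for simulated two-probe nuclei.

    Semi-axis ranges loosely follow cultured fibroblast nuclei (flattened
    ellipsoids ~14-18 μm wide, ~6 μm tall).  The subtelomeric probe sits at
    a controlled radial fraction of the envelope; the cluster probe is
    displaced from it by a controlled center separation in a uniform random
    direction (resampled until inside the nucleus).
    """

    condition: str = "control_like"
    n_nuclei: int = 30
    a_range: tuple[float, float] = (6.0, 9.0)
    b_range: tuple[float, float] = (5.0, 8.0)
    c_range: tuple[float, float] = (2.5, 3.5)
    radial_fraction_mean: float = 0.92
    radial_fraction_sd: float = 0.03
    separation_mean_um: float = 0.25
    separation_sd_um: float = 0.10
    probe_volume_mean_um3: float = 0.15
    probe_volume_sd_um3: float = 0.04
    voxel_um: tuple[float, float, float] | None = None
    max_resample: int = 1000

    def validate(self) -> None:
        if self.n_nuclei < 1:
            raise ValueError("n_nuclei must be >= 1")
        if not 0 <= self.radial_fraction_mean < 1:
            raise ValueError("radial_fraction_mean must be in [0, 1)")
        if self.separation_mean_um < 0:
            raise ValueError("separation must be >= 0")


def control_like_nuclei_config(**overrides) -> NucleusSimConfig:
    """Envelope-proximal, colocalized probe pairs (qualitative preset)."""
    return NucleusSimConfig(condition="control_like", **overrides)


def case_like_nuclei_config(**overrides) -> NucleusSimConfig:
    """Interior, separated probe pairs (qualitative preset)."""
    defaults = dict(
        condition="case_like",
        radial_fraction_mean=0.60,
        radial_fraction_sd=0.10,
        separation_mean_um=1.6,
        separation_sd_um=0.40,
    )
    defaults.update(overrides)
    return NucleusSimConfig(**defaults)


@dataclass
class NucleusTruthRecord:
    nucleus_id: str
    s_subtel: float
    s_cluster: float
    separation_um: float
    colocalized_overlap: bool
    colocalized_threshold: bool


@dataclass
class NucleiTruth:
    records: list[NucleusTruthRecord]
    config: NucleusSimConfig

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_records([asdict(r) for r in self.records])


def _uniform_direction(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _quantize(point: np.ndarray, voxel: tuple[float, float, float]) -> np.ndarray:
    v = np.asarray(voxel, float)
    return np.round(point / v) * v


def generate_nuclei(
    config: NucleusSimConfig | None = None,
    seed: int | None = 0,
    coloc_threshold_um: float = 0.5,
) -> tuple[dict[str, NucleusGeometry], list[ProbeSignal], NucleiTruth]:
    """Simulate ellipsoidal nuclei with two-channel probe pairs.

    Truth records each subtelomeric probe's exact radial scale fraction, the
    cluster probe's analytic scale fraction, the planted center separation
    and the intended colocalization status under both calling modes (from
    the pre-quantization coordinates).
    """
    config = config or NucleusSimConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    nuclei: dict[str, NucleusGeometry] = {}
    probes: list[ProbeSignal] = []
    records: list[NucleusTruthRecord] = []
    for i in range(config.n_nuclei):
        nid = f"{config.condition}-n{i + 1:03d}"
        axes = np.array([
            rng.uniform(*config.a_range),
            rng.uniform(*config.b_range),
            rng.uniform(*config.c_range),
        ])
        center = rng.uniform(20.0, 60.0, size=3)
        nuc = NucleusGeometry.from_ellipsoid(nid, center, axes)

        s1 = float(np.clip(
            rng.normal(config.radial_fraction_mean, config.radial_fraction_sd),
            0.0, 0.995,
        ))
        u = _uniform_direction(rng)
        p_subtel = center + s1 * ellipsoid_surface_point(axes, u)

        d = max(0.0, float(rng.normal(config.separation_mean_um, config.separation_sd_um))) \
            if config.separation_sd_um > 0 else config.separation_mean_um
        for attempt in range(config.max_resample):
            p_cluster = p_subtel + d * _uniform_direction(rng)
            if nuc.contains(p_cluster[None, :])[0]:
                break
        else:
            raise RuntimeError(
                f"could not place cluster probe inside {nid!r} after "
                f"{config.max_resample} resamples (separation {d:.3g} μm too "
                "large for the geometry)"
            )
        s2 = float(np.sqrt(np.sum(((p_cluster - center) / axes) ** 2)))

        vol1, vol2 = np.maximum(
            rng.normal(config.probe_volume_mean_um3, config.probe_volume_sd_um3, 2),
            0.01,
        )
        r1 = (3 * vol1 / (4 * math.pi)) ** (1 / 3)
        r2 = (3 * vol2 / (4 * math.pi)) ** (1 / 3)
        if config.voxel_um is not None:
            p_subtel = _quantize(p_subtel, config.voxel_um)
            p_cluster = _quantize(p_cluster, config.voxel_um)

        probes.append(ProbeSignal(nid, SUBTEL_CHANNEL, p_subtel, float(vol1)))
        probes.append(ProbeSignal(nid, CLUSTER_CHANNEL, p_cluster, float(vol2)))
        nuclei[nid] = nuc
        records.append(NucleusTruthRecord(
            nucleus_id=nid,
            s_subtel=s1,
            s_cluster=s2,
            separation_um=d,
            colocalized_overlap=d <= r1 + r2,
            colocalized_threshold=d <= coloc_threshold_um,
        ))
    return nuclei, probes, NucleiTruth(records, config)


# ---------------------------------------------------------------------------
# constructed reproduction fixture (synthetic stand-in)
# ---------------------------------------------------------------------------

#: id of the top up-regulated assay in the constructed fixture
REFERENCE_TARGET_ID = "synmiR-376b-like"
REFERENCE_CLUSTER_ID = "14q32"

#: outcome of the selection pipeline on the constructed fixture, exact by
#: construction (see synthetic_reference_panel)
REFERENCE_EXPECTED = {
    "input_mirnas": 375,
    "retained": 188,
    "reference_set_size": 114,
    "de_total": 14,
    "de_up": 8,
    "de_down": 6,
    "up_in_cluster": 7,
    "target_mean_fc": 2.22,
}


def synthetic_reference_panel() -> tuple[CqPanel, MirnaAnnotation, dict]:
    """Deterministic constructed fixture emulating a deposited miRNome panel.

    Synthetic stand-in for a 375-assay x 15-sample deposited table.  The
    matrix is built so that the selection pipeline's outcome is known
    exactly, with no random tuning:

    * 187 assays read Cq 39 in every sample -> excluded by the detection
      filter; 188 retained.
    * 114 retained assays are detected (Cq <= 35) in every sample -> the
      global-mean reference set; the remaining 74 carry one high-Cq control
      cell (36.5 + shift) and stay out of the reference set.
    * Within-sample noise uses paired +v/-v patterns summing to zero across
      the reference set and to zero within each group, and the planted case
      effects sum to zero over the 14 DE assays, so each sample's global
      mean is exactly baseline + shift and every non-DE assay tests at
      p = 1 while every planted assay is strongly significant.
    * The top assay carries a case effect of exactly log2(2.22) with no
      row noise, so its mean case fold-change is exactly 2.22.
    * The annotation places 7 of the 8 up-regulated assays (and none of the
      down-regulated) in the locus cluster "14q32" together with 8 retained
      and 9 excluded unrelated members.

    Returns ``(panel, annotation, expected_counts)``.
    """
    n_case, n_ctrl = 8, 7
    samples = [f"case-{i+1:02d}" for i in range(n_case)] + \
              [f"ctrl-{i+1:02d}" for i in range(n_ctrl)]
    groups = pd.Series(["case"] * n_case + ["control"] * n_ctrl, index=samples)
    passages = pd.Series(
        ["P12"] * 5 + ["P20"] * 3 + ["P12"] * 5 + ["P20"] * 2, index=samples
    )
    shifts = np.linspace(-0.5, 0.5, len(samples))

    a = 0.15  # within-sample pattern amplitude, cycles
    pat_case = np.array([+a, -a] * 4)
    pat_ctrl = np.array([+a, -a, +a, -a, +a, -a, 0.0])
    pattern = np.concatenate([pat_case, pat_ctrl])

    target_effect = math.log2(2.22)
    up_effect = 1.3
    down_effect = -(target_effect + 7 * up_effect) / 6.0  # effects sum to 0

    ids: list[str] = []
    rows: list[np.ndarray] = []
    is_case = np.array([1.0] * n_case + [0.0] * n_ctrl)

    def add_row(mid: str, baseline: float, effect: float, noise: np.ndarray) -> None:
        ids.append(mid)
        rows.append(baseline + shifts - effect * is_case + noise)

    zero = np.zeros(len(samples))
    # 14 DE assays (rows 0..13); the target and one down assay are noise-free
    add_row(REFERENCE_TARGET_ID, 24.0, target_effect, zero)
    add_row("synmiR-dn-1", 27.0, down_effect, zero)
    de_rest = [(f"synmiR-up-{i}", up_effect) for i in range(2, 9)] + \
              [(f"synmiR-dn-{i}", down_effect) for i in range(2, 7)]
    for j, (mid, eff) in enumerate(de_rest):
        sign = +1.0 if j % 2 == 0 else -1.0
        add_row(mid, 24.5 + 0.3 * j, eff, sign * pattern)

    # 100 reference non-DE assays in +v/-v pairs (rows 14..113)
    for j in range(100):
        sign = +1.0 if j % 2 == 0 else -1.0
        add_row(f"synmiR-ref-{j+1:03d}", 22.0 + 0.12 * j, 0.0, sign * pattern)

    # 74 retained, non-reference assays: one control cell above the cutoff
    spike = np.zeros(len(samples))
    spike[-1] = 1.0
    for j in range(74):
        baseline = 32.5 + 0.02 * j
        noise = (36.5 - baseline - shifts[-1]) * spike  # ctrl-07 reads 36.5 raw
        add_row(f"synmiR-high-{j+1:03d}", baseline, 0.0, noise)

    # 187 not-expressed assays
    for j in range(187):
        add_row(f"synmiR-off-{j+1:03d}", 39.0, 0.0, zero)

    cq = pd.DataFrame(np.vstack(rows), index=ids, columns=samples)
    panel = CqPanel(cq, groups, passages)

    cluster_members = (
        [REFERENCE_TARGET_ID]
        + [f"synmiR-up-{i}" for i in range(2, 8)]          # 7 of the 8 up
        + [f"synmiR-ref-{j+1:03d}" for j in range(8)]       # retained, non-DE
        + [f"synmiR-off-{j+1:03d}" for j in range(9)]       # excluded members
    )
    annotation = _panel_annotation(ids, cluster_members, REFERENCE_CLUSTER_ID)
    return panel, annotation, dict(REFERENCE_EXPECTED)
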