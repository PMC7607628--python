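"""Seeded synthetic-data generators for every pipeline stage.

Three generators emit the exact table dialects the analysis modules read,
plus sidecar truth labels, so the whole pipeline is testable without any
external data:

* :func:`simulate_trial` — a cohort of patients drawn from a best-response
  category mixture.  Lesion-diameter trajectories are constructed backward
  from the intended RECIST category (piecewise-linear in sum-of-diameters
  space), so re-classifying the generated assessments recovers the planted
  category.  PFS and OS times are exponential at the configured medians
  (independent draws per endpoint), right-censored at the follow-up
  horizon.
* :func:`simulate_rppa` — an antibody × sample log2 matrix with a planted
  pathway-activation factor (positive loading on the six positive-arm
  antibodies, negative on PTEN/INPP4B) and an on-treatment shift applied to
  the key downstream antibodies of paired samples.
* :func:`simulate_variants` — a MAF-like variant table in which samples are
  pathway-altered with a configured probability, drawing events from the
  canonical alteration templates (PIK3CA E542K, AKT1 E17K, AKT1
  amplification, PTEN D24H, PTEN K237fs, PTEN deep deletion).

All generators are pure functions of (config, seed); per-patient /
per-sample sub-streams are derived deterministically from the global seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rppa import DEFAULT_KEY_ANTIBODIES, DEFAULT_NODE_MAP

__all__ = [
    "TrialSimConfig",
    "RppaSimConfig",
    "VariantSimConfig",
    "TrialBundle",
    "RppaBundle",
    "VariantBundle",
    "simulate_trial",
    "simulate_rppa",
    "simulate_variants",
    "TABLE2_CATEGORY_PROBS",
]

CATEGORIES = ("CR", "PR", "SD_long", "SD_short", "PD_fast", "NE")

# Best-response mixture matching the published 50-patient cohort:
# no responses, 12% prolonged SD, 22% short SD, 40% PD, 26% non-evaluable.
TABLE2_CATEGORY_PROBS = (0.0, 0.0, 0.12, 0.22, 0.40, 0.26)


@dataclass(frozen=True)
class TrialSimConfig:
    n_patients: int = 50
    category_probs: tuple[float, ...] = TABLE2_CATEGORY_PROBS
    pfs_median_days: float = 54.75  # 1.8 months
    os_median_days: float = 340.9  # 11.2 months
    assessment_interval_days: int = 56  # every 2 cycles of 28 days
    max_followup_days: int = 1200
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.category_probs) != len(CATEGORIES):
            raise ValueError(f"category_probs must have {len(CATEGORIES)} entries")
        if abs(sum(self.category_probs) - 1.0) > 1e-9 or min(self.category_probs) < 0:
            raise ValueError("category_probs must be non-negative and sum to 1")
        if self.pfs_median_days <= 0 or self.os_median_days <= 0:
            raise ValueError("median event times must be positive")
        if self.assessment_interval_days <= 0:
            raise ValueError("assessment interval must be positive")


@dataclass(frozen=True)
class TrialBundle:
    assessments: pd.DataFrame  # patient_id, day, lesion_id, diameter_mm, new_lesion
    pfs: pd.DataFrame  # patient_id, time_days, event
    os: pd.DataFrame  # patient_id, time_days, event
    truth: pd.DataFrame  # patient_id, category


# sum-of-diameter multipliers per post-baseline visit, built backward from
# the intended RECIST category (visit spacing = assessment_interval_days)
_TRAJECTORIES: dict[str, tuple[tuple[float, bool], ...]] = {
    # (sum multiplier vs baseline, new_lesion)
    "CR": ((0.0, False), (0.0, False)),
    "PR": ((0.60, False), (0.55, False), (0.58, False)),
    "SD_long": ((0.95, False), (0.90, False), (0.92, False), (1.50, True)),
    "SD_short": ((0.95, False), (1.45, False)),
    "PD_fast": ((1.35, False),),
    "NE": (),
}


def simulate_trial(cfg: TrialSimConfig) -> TrialBundle:
    """Generate a synthetic trial cohort (assessments + survival records)."""
    rng_cat = np.random.default_rng([cfg.seed, 0])
    cats = rng_cat.choice(
        len(CATEGORIES), size=cfg.n_patients, p=list(cfg.category_probs)
    )
    rows = []
    pfs_rows = []
    os_rows = []
    truth_rows = []
    log2 = math.log(2.0)
    for i in range(cfg.n_patients):
        pid = f"P{i + 1:03d}"
        cat = CATEGORIES[cats[i]]
        rng = np.random.default_rng([cfg.seed, 1, i])
        n_lesions = int(rng.integers(1, 4))
        # baseline sum >= 30 mm so the 5 mm absolute progression rule never
        # blocks a planted >= 20% increase
        diams = rng.uniform(15.0, 50.0, size=n_lesions)
        diams *= max(1.0, 30.0 / diams.sum())
        for j, d in enumerate(diams):
            rows.append((pid, 0, f"L{j + 1}", round(float(d), 1), False))
        base = np.array([round(float(d), 1) for d in diams])
        for k, (mult, new_lesion) in enumerate(_TRAJECTORIES[cat]):
            day = (k + 1) * cfg.assessment_interval_days
            if day > cfg.max_followup_days:
                break
            for j, d in enumerate(base):
                rows.append((pid, day, f"L{j + 1}", round(float(d * mult), 2), new_lesion))
        # exponential event times at the configured medians, independent
        # draws per endpoint, censored at the follow-up horizon
        t_pfs = max(1.0, rng.exponential(cfg.pfs_median_days / log2))
        t_os = max(1.0, rng.exponential(cfg.os_median_days / log2))
        pfs_rows.append(
            (pid, min(t_pfs, cfg.max_followup_days), t_pfs <= cfg.max_followup_days)
        )
        os_rows.append(
            (pid, min(t_os, cfg.max_followup_days), t_os <= cfg.max_followup_days)
        )
        truth_rows.append((pid, cat))
    return TrialBundle(
        assessments=pd.DataFrame(
            rows, columns=["patient_id", "day", "lesion_id", "diameter_mm", "new_lesion"]
        ),
        pfs=pd.DataFrame(pfs_rows, columns=["patient_id", "time_days", "event"]),
        os=pd.DataFrame(os_rows, columns=["patient_id", "time_days", "event"]),
        truth=pd.DataFrame(truth_rows, columns=["patient_id", "category"]),
    )


@dataclass(frozen=True)
class RppaSimConfig:
    n_antibodies: int = 30
    n_samples: int = 20  # total matrix columns, paired columns included
    activation_fraction: float = 0.5
    activation_effect_sd: float = 2.0
    treatment_effect: float = -1.0
    noise_sd: float = 0.3
    n_pairs: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.activation_fraction <= 1:
            raise ValueError("activation_fraction must lie in [0,1]")
        if self.noise_sd <= 0 or self.activation_effect_sd <= 0:
            raise ValueError("SDs must be positive")
        if self.n_pairs * 2 > self.n_samples:
            raise ValueError("n_pairs exceeds half the sample budget")
        core = sum(len(v) for v in DEFAULT_NODE_MAP.values())
        if self.n_antibodies < core:
            raise ValueError(f"need at least {core} antibodies for the score nodes")


@dataclass(frozen=True)
class RppaBundle:
    matrix: pd.DataFrame  # antibodies x samples, raw log2 scale
    pairs: pd.DataFrame  # patient_id, baseline_sample, ontx_sample
    truth: pd.DataFrame  # sample, patient_id, timepoint, activated


def _rppa_antibodies(n: int) -> list[str]:
    core = [a for abs_ in DEFAULT_NODE_MAP.values() for a in abs_]
    filler = [f"AB{k:03d}" for k in range(1, n - len(core) + 1)]
    return core + filler


def simulate_rppa(cfg: RppaSimConfig) -> RppaBundle:
    """Generate an RPPA matrix with a planted activation factor and pairs."""
    antibodies = _rppa_antibodies(cfg.n_antibodies)
    pos_abs = {a for n in ("pAkt", "pmTOR", "pGSK3", "pS6K", "pS6", "p4EBP1")
               for a in DEFAULT_NODE_MAP[n]}
    neg_abs = {a for n in ("INPP4B", "PTEN") for a in DEFAULT_NODE_MAP[n]}
    loading = np.array(
        [1.0 if a in pos_abs else -1.0 if a in neg_abs else 0.0 for a in antibodies]
    )
    key_idx = np.array([antibodies.index(a) for a in DEFAULT_KEY_ANTIBODIES])

    rng0 = np.random.default_rng([cfg.seed, 0])
    baseline_level = rng0.normal(0.0, 1.0, size=len(antibodies))

    n_patients = cfg.n_samples - cfg.n_pairs
    cols: dict[str, np.ndarray] = {}
    pair_rows = []
    truth_rows = []
    for i in range(n_patients):
        pid = f"R{i + 1:02d}"
        rng = np.random.default_rng([cfg.seed, 1, i])
        activated = bool(rng.random() < cfg.activation_fraction)
        factor = cfg.activation_effect_sd if activated else 0.0
        base = (
            baseline_level
            + factor * loading
            + rng.normal(0.0, cfg.noise_sd, size=len(antibodies))
        )
        bl_name = f"{pid}_BL"
        cols[bl_name] = base
        truth_rows.append((bl_name, pid, "baseline", activated))
        if i < cfg.n_pairs:
            ontx = base + rng.normal(0.0, cfg.noise_sd, size=len(antibodies))
            ontx[key_idx] += cfg.treatment_effect
            tx_name = f"{pid}_TX"
            cols[tx_name] = ontx
            pair_rows.append((pid, bl_name, tx_name))
            truth_rows.append((tx_name, pid, "ontx", activated))
    matrix = pd.DataFrame(cols, index=antibodies)
    return RppaBundle(
        matrix=matrix,
        pairs=pd.DataFrame(
            pair_rows, columns=["patient_id", "baseline_sample", "ontx_sample"]
        ),
        truth=pd.DataFrame(
            truth_rows, columns=["sample", "patient_id", "timepoint", "activated"]
        ),
    )


@dataclass(frozen=True)
class VariantSimConfig:
    n_samples: int = 27
    pathway_alteration_prob: float = 6 / 27
    gene_weights: tuple[float, ...] = (1, 1, 1, 1, 1, 1)  # over _EVENT_TEMPLATES
    background_prob: float = 0.3  # chance of a non-qualifying passenger variant
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.pathway_alteration_prob <= 1:
            raise ValueError("pathway_alteration_prob must lie in [0,1]")
        if len(self.gene_weights) != len(_EVENT_TEMPLATES) or min(self.gene_weights) < 0:
            raise ValueError("gene_weights must be non-negative, one per event template")


# canonical pathway-qualifying event templates
_EVENT_TEMPLATES = (
    ("PIK3CA", "MISSENSE", "p.E542K", None),
    ("AKT1", "MISSENSE", "p.E17K", None),
    ("AKT1", "AMPLIFICATION", None, 1.8),
    ("PTEN", "MISSENSE", "p.D24H", None),
    ("PTEN", "FRAMESHIFT", "p.K237fs", None),
    ("PTEN", "DELETION", None, -2.9),
)

_BACKGROUND_TEMPLATES = (
    ("TP53", "SPLICE", "p.X126_splice", None),
    ("RB1", "SPLICE", "p.X405_splice", None),
    ("TP53", "MISSENSE", "p.R273H", None),
)


@dataclass(frozen=True)
class VariantBundle:
    variants: pd.DataFrame  # sample_id, Hugo_Symbol, Variant_Classification, HGVSp_Short, cn_log_ratio
    truth: pd.DataFrame  # sample_id, altered


def simulate_variants(cfg: VariantSimConfig) -> VariantBundle:
    """Generate a MAF-like variant table with planted pathway alterations."""
    w = np.array(cfg.gene_weights, dtype=float)
    w = w / w.sum()
    rows = []
    truth_rows = []
    for i in range(cfg.n_samples):
        sid = f"V{i + 1:03d}"
        rng = np.random.default_rng([cfg.seed, 2, i])
        altered = bool(rng.random() < cfg.pathway_alteration_prob)
        if altered:
            gene, vclass, hgvsp, cn = _EVENT_TEMPLATES[int(rng.choice(len(w), p=w))]
            rows.append((sid, gene, vclass, hgvsp, cn))
        if rng.random() < cfg.background_prob:
            gene, vclass, hgvsp, cn = _BACKGROUND_TEMPLATES[
                int(rng.integers(len(_BACKGROUND_TEMPLATES)))
            ]
            rows.append((sid, gene, vclass, hgvsp, cn))
        truth_rows.append((sid, altered))
    return VariantBundle(
        variants=pd.DataFrame(
            rows,
            columns=[
                "sample_id", "Hugo_Symbol", "Variant_Classification",
                "HGVSp_Short", "cn_log_ratio",
            ],
        ),
        truth=pd.DataFrame(truth_rows, columns=["sample_id", "altered"]),
    )
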