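"""Published study inputs as patient-level fixture builders.

The trial's patient-level data are not public; what is public are summary
tables.  This module reconstructs patient-level inputs that realize exactly
those summaries, so the pipeline's cohort statistics can be recomputed from
first principles:

* the protocol monitoring rule (Beta(0.5, 9.5) prior, reference rate 0.05,
  posterior threshold 0.95, 29-patient interim, 50-patient total);
* the 50-patient best-overall-response distribution (no confirmed CR/PR,
  6 SD ≥ 4 months — one of them an unconfirmed PR — 11 SD < 4 months,
  20 PD, 13 non-evaluable);
* the 27-patient sequencing cohort: six pathway-altered samples carrying
  the reported events (PIK3CA E542K; AKT1 E17K; AKT1 amplification; PTEN
  D24H; PTEN K237fs; PTEN deep deletion, log ratio −2.87) with best
  responses 3 SD / 2 PD / 1 NE, and 21 unaltered samples with best
  responses 1 SD ≥ 4 months / 4 SD < 4 months / 7 PD / 9 NE.
"""

from __future__ import annotations

from .design import BetaDistribution, MonitoringRule
from .endpoints import BestOverallResponse, BorCategory
from .genomics import AlterationType, VariantRecord

__all__ = [
    "study_monitoring_rule",
    "best_response_cohort",
    "sequencing_cohort",
    "INTERIM_SUCCESSES",
    "INTERIM_N_OBSERVED",
]

# first-stage conduct: one extra patient was enrolled beyond the planned 29,
# and 3 of the first 30 achieved clinical benefit
INTERIM_SUCCESSES = 3
INTERIM_N_OBSERVED = 30


def study_monitoring_rule() -> MonitoringRule:
    """The protocol's Bayesian futility-monitoring rule."""
    return MonitoringRule(
        prior=BetaDistribution(0.5, 9.5),
        p_ref=0.05,
        threshold=0.95,
        interim_n=29,
        total_n=50,
    )


def best_response_cohort() -> list[BestOverallResponse]:
    """The 50-patient best-overall-response distribution, patient-level."""
    cohort: list[BestOverallResponse] = []
    # 6 patients with SD >= 4 months; one carried an unconfirmed PR
    cohort.append(
        BestOverallResponse(
            category=BorCategory.SD, unconfirmed_pr_flag=True, sd_duration_days=140
        )
    )
    cohort += [
        BestOverallResponse(category=BorCategory.SD, sd_duration_days=d)
        for d in (112, 126, 140, 168, 224)
    ]
    # 11 patients with SD < 4 months
    cohort += [
        BestOverallResponse(category=BorCategory.SD, sd_duration_days=56)
        for _ in range(11)
    ]
    cohort += [BestOverallResponse(category=BorCategory.PD) for _ in range(20)]
    cohort += [BestOverallResponse(category=BorCategory.NE) for _ in range(13)]
    assert len(cohort) == 50
    return cohort


def sequencing_cohort() -> tuple[dict[str, list[VariantRecord]], dict[str, str]]:
    """Variant lists and response groups for the 27 sequenced patients.

    Returns (variants_by_sample, response_group_by_sample) with response
    groups in {"SD>=4mo", "SD<4mo", "PD", "NE"}.
    """
    variants: dict[str, list[VariantRecord]] = {f"S{i:02d}": [] for i in range(1, 28)}

    def v(sid, gene, atype, protein=None, cn=None):
        variants[sid].append(
            VariantRecord(
                sample_id=sid,
                gene=gene,
                alteration_type=AlterationType(atype),
                protein_change=protein,
                cn_log_ratio=cn,
            )
        )

    # six altered samples: best response 3 SD<4mo (both AKT1-altered and the
    # PTEN K237fs patient), 2 PD, 1 NE
    v("S01", "AKT1", "MISSENSE", "p.E17K")
    v("S02", "AKT1", "AMPLIFICATION", cn=1.8)
    v("S03", "PTEN", "FRAMESHIFT", "p.K237fs")
    v("S04", "PIK3CA", "MISSENSE", "p.E542K")
    v("S05", "PTEN", "MISSENSE", "p.D24H")
    v("S06", "PTEN", "DELETION", cn=-2.87)
    # the one clinical-benefit patient with sequencing carried TP53/RB1
    # splice variants but nothing in the pathway gene set
    v("S07", "TP53", "SPLICE", "p.X126_splice")
    v("S07", "RB1", "SPLICE", "p.X405_splice")

    groups: dict[str, str] = {}
    for sid in ("S01", "S02", "S03"):
        groups[sid] = "SD<4mo"
    groups["S04"] = "PD"
    groups["S05"] = "PD"
    groups["S06"] = "NE"
    # 21 unaltered: 1 SD>=4mo, 4 SD<4mo, 7 PD, 9 NE
    groups["S07"] = "SD>=4mo"
    for sid in ("S08", "S09", "S10", "S11"):
        groups[sid] = "SD<4mo"
    for i in range(12, 19):
        groups[f"S{i:02d}"] = "PD"
    for i in range(19, 28):
        groups[f"S{i:02d}"] = "NE"
    assert len(groups) == 27
    return variants, groups
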