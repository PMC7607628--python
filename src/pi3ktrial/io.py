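"""Table readers/writers and configuration for the pipeline.

All tables are UTF-8 text with a header row: CSVs for clinical tables,
TSVs for the RPPA matrix and MAF-like variant tables.  Readers validate
the schema and raise :class:`SchemaError` naming the offending file and
column; values round-trip through write/read unchanged to float precision.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from .design import BetaDistribution, MonitoringRule
from .genomics import AlterationType, VariantRecord
from .rppa import NodeMap, RppaMatrix
from .survival import SurvivalRecord

logger = logging.getLogger("pi3ktrial")

__all__ = [
    "SchemaError",
    "read_assessments",
    "write_assessments",
    "read_survival",
    "write_survival",
    "read_rppa",
    "write_rppa",
    "read_pairs",
    "write_pairs",
    "read_maf",
    "write_maf",
    "read_node_map",
    "read_design_config",
    "write_run_meta",
]


class SchemaError(ValueError):
    """An input table violates its documented schema."""


def _require_columns(df: pd.DataFrame, cols: list[str], path: str | Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


ASSESSMENT_COLUMNS = ["patient_id", "day", "lesion_id", "diameter_mm", "new_lesion"]


def read_assessments(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ASSESSMENT_COLUMNS, path)
    if df.empty:
        raise SchemaError(f"{path}: assessment table is empty")
    df["new_lesion"] = df["new_lesion"].astype(bool)
    by_patient = df.groupby("patient_id")["day"]
    if (by_patient.apply(lambda s: (s.diff().dropna() < 0).any())).any():
        logger.warning("%s: days not sorted within patients; sorting", path)
    return df.sort_values(["patient_id", "day", "lesion_id"]).reset_index(drop=True)


def write_assessments(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, columns=ASSESSMENT_COLUMNS)


def read_survival(path: str | Path) -> list[SurvivalRecord]:
    df = pd.read_csv(path)
    _require_columns(df, ["patient_id", "time_days", "event"], path)
    if df.empty:
        raise SchemaError(f"{path}: survival table is empty")
    return [
        SurvivalRecord(str(r.patient_id), float(r.time_days), bool(r.event))
        for r in df.itertuples()
    ]


def write_survival(records: list[SurvivalRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(r.patient_id, r.time_days, int(r.event)) for r in records],
        columns=["patient_id", "time_days", "event"],
    ).to_csv(path, index=False)


def read_rppa(path: str | Path) -> RppaMatrix:
    """Read an antibody × sample TSV; first column holds antibody names."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty or df.shape[1] == 0:
        raise SchemaError(f"{path}: RPPA matrix is empty")
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise SchemaError(
            f"{path}: missing values in sample column(s) {bad}; "
            "imputation is not supported"
        )
    df.index.name = "antibody"
    return RppaMatrix(values=df)


def write_rppa(m: RppaMatrix, path: str | Path) -> None:
    out = m.values.copy()
    out.index.name = "antibody"
    out.to_csv(path, sep="\t")


def read_pairs(path: str | Path) -> list[tuple[str, str, str]]:
    df = pd.read_csv(path)
    _require_columns(df, ["patient_id", "baseline_sample", "ontx_sample"], path)
    return [
        (str(r.patient_id), str(r.baseline_sample), str(r.ontx_sample))
        for r in df.itertuples()
    ]


def write_pairs(pairs: list[tuple[str, str, str]], path: str | Path) -> None:
    pd.DataFrame(
        pairs, columns=["patient_id", "baseline_sample", "ontx_sample"]
    ).to_csv(path, index=False)


# accepted Variant_Classification vocabulary, including common MAF spellings
_MAF_CLASS = {
    "MISSENSE": AlterationType.MISSENSE,
    "MISSENSE_MUTATION": AlterationType.MISSENSE,
    "TRUNCATING": AlterationType.TRUNCATING,
    "NONSENSE_MUTATION": AlterationType.TRUNCATING,
    "FRAMESHIFT": AlterationType.FRAMESHIFT,
    "FRAME_SHIFT_DEL": AlterationType.FRAMESHIFT,
    "FRAME_SHIFT_INS": AlterationType.FRAMESHIFT,
    "SPLICE": AlterationType.SPLICE,
    "SPLICE_SITE": AlterationType.SPLICE,
    "AMPLIFICATION": AlterationType.AMPLIFICATION,
    "AMP": AlterationType.AMPLIFICATION,
    "DELETION": AlterationType.DELETION,
    "DEL": AlterationType.DELETION,
}

MAF_COLUMNS = [
    "sample_id", "Hugo_Symbol", "Variant_Classification", "HGVSp_Short", "cn_log_ratio",
]


def read_maf(path: str | Path) -> dict[str, list[VariantRecord]]:
    """Read a MAF-like TSV into per-sample variant lists."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, MAF_COLUMNS, path)
    out: dict[str, list[VariantRecord]] = {}
    for i, r in enumerate(df.itertuples()):
        key = str(r.Variant_Classification).upper()
        if key not in _MAF_CLASS:
            raise SchemaError(
                f"{path}: line {i + 2}: unknown Variant_Classification "
                f"{r.Variant_Classification!r}"
            )
        cn = None if pd.isna(r.cn_log_ratio) else float(r.cn_log_ratio)
        protein = None if pd.isna(r.HGVSp_Short) else str(r.HGVSp_Short)
        out.setdefault(str(r.sample_id), []).append(
            VariantRecord(
                sample_id=str(r.sample_id),
                gene=str(r.Hugo_Symbol),
                alteration_type=_MAF_CLASS[key],
                protein_change=protein,
                cn_log_ratio=cn,
            )
        )
    return out


def write_maf(df: pd.DataFrame, path: str | Path) -> None:
    _require_columns(df, MAF_COLUMNS, path)
    df.to_csv(path, sep="\t", index=False, columns=MAF_COLUMNS)


def read_node_map(path: str | Path) -> NodeMap:
    """Read a YAML mapping of score node → list of antibody names."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: node map must be a mapping")
    return NodeMap(mapping={k: tuple(v) for k, v in raw.items()})


def read_design_config(path: str | Path) -> MonitoringRule:
    """Read a monitoring-rule config (YAML or JSON by extension)."""
    p = Path(path)
    with open(p) as fh:
        raw = json.load(fh) if p.suffix == ".json" else yaml.safe_load(fh)
    required = ["prior_alpha", "prior_beta", "p_ref", "threshold", "interim_n", "total_n"]
    missing = [k for k in required if k not in raw]
    if missing:
        raise SchemaError(f"{path}: missing design key(s) {missing}")
    return MonitoringRule(
        prior=BetaDistribution(float(raw["prior_alpha"]), float(raw["prior_beta"])),
        p_ref=float(raw["p_ref"]),
        threshold=float(raw["threshold"]),
        interim_n=int(raw["interim_n"]),
        total_n=int(raw["total_n"]),
    )


def write_run_meta(path: str | Path, seed: int | None, options: dict) -> None:
    """Record version, seed and a config hash sufficient to reproduce a run."""
    from . import __version__

    payload = json.dumps(options, sort_keys=True, default=str)
    meta = {
        "version": __version__,
        "seed": seed,
        "rng": "numpy.random.default_rng (PCG64)",
        "config_hash": hashlib.sha256(payload.encode()).hexdigest(),
        "options": options,
    }
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
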