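"""Eight-criterion hard filtering of annotated somatic variant tables.

The filter consumes per-region-sample variant calls that already carry
read evidence (depth, alt-supporting reads, per-strand alt counts) and
annotations (gene, functional region, population allele frequencies,
deleteriousness predictions).  Calls are kept only if, in order:

1. strand bias < 0.9 (bias = majority-strand fraction of alt reads);
2. total coverage >= 20 and alt-supporting reads >= 8;
3. variant allele frequency >= 0.1;
4. not a common dbSNP polymorphism (AF >= 1%);
5. not a common SNP in the CONVERGE Chinese-population catalogue;
6. not a 1000 Genomes gold-standard INDEL;
7. AF <= 0.015 in each of 1000 Genomes, ESP6500 and ExAC;
8. located in an exonic or splicing region.

Rejections are attributed to the first failing criterion in this
order.  Missing population AFs count as "not common" (absence of
database evidence).  Upstream variant calling and annotation are out of
scope: this module starts from their tabular output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical column order of the TSV dialect.
TSV_COLUMNS = [
    "patient",
    "sample",
    "chrom",
    "pos",
    "ref",
    "alt",
    "depth",
    "alt_reads",
    "plus_strand_alt",
    "minus_strand_alt",
    "gene",
    "func",
    "exonic_func",
    "dbsnp_af",
    "converge_af",
    "kg_af",
    "esp_af",
    "exac_af",
    "sift",
    "polyphen",
]
#: Optional extras the simulator emits and downstream stages use.
OPTIONAL_COLUMNS = ["context", "kg_gold_indel", "cosmic_flag"]

_AF_COLUMNS = ["dbsnp_af", "converge_af", "kg_af", "esp_af", "exac_af"]

#: Rejection labels in attribution order (criteria 1-8; criterion 2
#: contributes two labels so reports can distinguish low coverage from
#: low alt-read support).
CRITERIA = [
    "strand_bias",
    "depth",
    "alt_reads",
    "vaf",
    "dbsnp_af",
    "converge",
    "kg_gold_indel",
    "pop_af_0.015",
    "region",
]


@dataclass
class FilterConfig:
    """Thresholds of the somatic hard filter (defaults as published)."""

    max_strand_bias: float = 0.9  # reject if bias >= this
    min_depth: int = 20
    min_alt_reads: int = 8
    min_vaf: float = 0.1
    max_dbsnp_af: float = 0.01  # reject if AF >= this
    max_converge_af: float = 0.01  # "common" CONVERGE SNP
    max_pop_af: float = 0.015  # reject if AF > this in any of 1000G/ESP/ExAC
    allowed_regions: tuple[str, ...] = ("exonic", "splicing", "exonic;splicing")


@dataclass
class FilterReport:
    """Per-criterion rejection counts; first-failing attribution."""

    rejections: dict[str, int]
    n_pass: int
    n_input: int
    criteria: list[str] = field(default_factory=lambda: list(CRITERIA))

    def __post_init__(self) -> None:
        if sum(self.rejections.values()) + self.n_pass != self.n_input:
            raise ValueError("rejections + passes must equal input size")

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_input": self.n_input,
                "n_pass": self.n_pass,
                "rejections": {c: self.rejections.get(c, 0) for c in self.criteria},
            },
            indent=2,
            sort_keys=True,
        )

    def __str__(self) -> str:
        lines = [f"input records : {self.n_input}", f"passing       : {self.n_pass}"]
        for c in self.criteria:
            lines.append(f"rejected[{c}] : {self.rejections.get(c, 0)}")
        return "\n".join(lines)


def variant_type(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    return "INS" if len(alt) > len(ref) else "DEL"


def _normalize_indel(ref: str, alt: str, pos: int) -> tuple[str, str, int]:
    """Left-trim the shared suffix/prefix beyond a single anchor base."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return ref, alt, pos


def annotate_evidence(records: pd.DataFrame) -> pd.DataFrame:
    """Derive ``vaf``, ``strand_bias`` and ``variant_type`` columns.

    Strand bias is the fraction of alt reads on the majority strand,
    ``max(plus, minus)/alt_reads``, computed from per-strand counts
    when present; an existing ``strand_bias`` column is kept for rows
    without strand counts.
    """
    df = records.copy()
    depth = df["depth"].to_numpy(dtype=float)
    alt = df["alt_reads"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        df["vaf"] = np.where(depth > 0, alt / depth, 0.0)
    if "plus_strand_alt" in df.columns and "minus_strand_alt" in df.columns:
        plus = df["plus_strand_alt"].to_numpy(dtype=float)
        minus = df["minus_strand_alt"].to_numpy(dtype=float)
        have = ~(np.isnan(plus) | np.isnan(minus))
        with np.errstate(divide="ignore", invalid="ignore"):
            bias = np.where(alt > 0, np.maximum(plus, minus) / alt, 0.0)
        prior = df["strand_bias"].to_numpy(dtype=float) if "strand_bias" in df else np.zeros(len(df))
        df["strand_bias"] = np.where(have, bias, prior)
    elif "strand_bias" not in df.columns:
        df["strand_bias"] = 0.0
    df["variant_type"] = [variant_type(r, a) for r, a in zip(df["ref"], df["alt"])]
    return df


def validate_records(records: pd.DataFrame) -> None:
    """Raise with row numbers for structurally invalid records."""
    required = ["patient", "sample", "chrom", "pos", "ref", "alt", "depth", "alt_reads"]
    missing = [c for c in required if c not in records.columns]
    if missing:
        raise ValueError(f"variant table missing required columns: {missing}")
    errors = []
    depth = records["depth"].to_numpy(dtype=float)
    alt = records["alt_reads"].to_numpy(dtype=float)
    pos = records["pos"].to_numpy(dtype=float)
    for i in np.flatnonzero(depth < 0):
        errors.append(f"row {i}: negative depth {depth[i]}")
    for i in np.flatnonzero(alt > depth):
        errors.append(f"row {i}: alt_reads {alt[i]} > depth {depth[i]}")
    for i in np.flatnonzero(pos < 1):
        errors.append(f"row {i}: position {pos[i]} < 1 (coordinates are 1-based)")
    if errors:
        raise ValueError("invalid variant records:\n" + "\n".join(errors))


def apply_somatic_filters(
    records: pd.DataFrame, thresholds: FilterConfig | None = None
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the eight somatic criteria; return passing rows and a report.

    Each rejected record is attributed to the first failing criterion
    in the published order.  The input is validated and evidence
    columns (vaf, strand bias, variant type) are derived if absent.
    """
    cfg = thresholds or FilterConfig()
    validate_records(records)
    df = annotate_evidence(records)
    n = len(df)
    if n == 0:
        return df, FilterReport(rejections={}, n_pass=0, n_input=0)

    def af(col):
        if col in df.columns:
            return df[col].to_numpy(dtype=float)
        return np.full(n, np.nan)

    dbsnp, conv = af("dbsnp_af"), af("converge_af")
    kg, esp, exac = af("kg_af"), af("esp_af"), af("exac_af")
    gold = (
        df["kg_gold_indel"].fillna(False).astype(bool).to_numpy()
        if "kg_gold_indel" in df.columns
        else np.zeros(n, dtype=bool)
    )
    func = df["func"].astype(str).str.lower() if "func" in df.columns else pd.Series("", index=df.index)
    is_indel = df["variant_type"].ne("SNV").to_numpy()

    fails = {
        "strand_bias": df["strand_bias"].to_numpy(dtype=float) >= cfg.max_strand_bias,
        "depth": df["depth"].to_numpy(dtype=float) < cfg.min_depth,
        "alt_reads": df["alt_reads"].to_numpy(dtype=float) < cfg.min_alt_reads,
        "vaf": df["vaf"].to_numpy(dtype=float) < cfg.min_vaf,
        "dbsnp_af": np.nan_to_num(dbsnp, nan=0.0) >= cfg.max_dbsnp_af,
        "converge": np.nan_to_num(conv, nan=0.0) >= cfg.max_converge_af,
        "kg_gold_indel": gold & is_indel,
        "pop_af_0.015": (
            (np.nan_to_num(kg, nan=0.0) > cfg.max_pop_af)
            | (np.nan_to_num(esp, nan=0.0) > cfg.max_pop_af)
            | (np.nan_to_num(exac, nan=0.0) > cfg.max_pop_af)
        ),
        "region": ~func.isin([r.lower() for r in cfg.allowed_regions]).to_numpy(),
    }
    reason = np.full(n, "", dtype=object)
    for crit in CRITERIA:
        mask = fails[crit] & (reason == "")
        reason[mask] = crit
    passing = df[reason == ""].copy()
    counts = {c: int((reason == c).sum()) for c in CRITERIA if (reason == c).any()}
    report = FilterReport(rejections=counts, n_pass=len(passing), n_input=n)
    return passing, report


# ---------------------------------------------------------------------------
# Readers / writers


def read_variants(path, dialect: str = "tsv", info_af_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a variant table from TSV or VCF into the canonical frame.

    Coordinates are 1-based throughout.  Missing population AFs are
    kept as NaN (distinct from an annotated 0).  INDEL alleles are
    left-normalised to a single anchor base.
    """
    if dialect == "tsv":
        df = read_variants_tsv(path)
    elif dialect == "vcf":
        df = read_variants_vcf(path, info_af_map=info_af_map)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    validate_records(df)
    return annotate_evidence(df)


def read_variants_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str, "patient": str})
    missing = [c for c in TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing TSV columns {missing}")
    norm = [
        _normalize_indel(r, a, p) for r, a, p in zip(df["ref"], df["alt"], df["pos"])
    ]
    df["ref"] = [x[0] for x in norm]
    df["alt"] = [x[1] for x in norm]
    df["pos"] = [x[2] for x in norm]
    if "kg_gold_indel" in df.columns:
        df["kg_gold_indel"] = df["kg_gold_indel"].fillna(0).astype(bool)
    return df


def read_variants_vcf(path, info_af_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read single- or multi-sample VCF 4.x (one row per sample carrying the call).

    Population AFs come from INFO tags (default mapping ``DBSNP_AF``,
    ``CONVERGE_AF``, ``KG_AF``, ``ESP_AF``, ``EXAC_AF``); gene and
    functional annotations from ``GENE``/``FUNC``/``EXONIC_FUNC``.
    Depth and alt reads come from FORMAT ``DP``/``AD``; per-strand alt
    counts from FORMAT ``SAC`` (plus,minus) when present.  An absent
    tag yields NaN, never 0.
    """
    import pysam

    amap = info_af_map or {
        "dbsnp_af": "DBSNP_AF",
        "converge_af": "CONVERGE_AF",
        "kg_af": "KG_AF",
        "esp_af": "ESP_AF",
        "exac_af": "EXAC_AF",
    }
    def ig(info, key, default=None):
        # pysam raises for INFO keys absent from the header
        try:
            return info.get(key, default)
        except (KeyError, ValueError):
            return default

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None:
                continue
            alt = rec.alts[0]
            info = rec.info
            base = {
                "chrom": rec.chrom,
                "pos": rec.pos,  # pysam exposes 1-based .pos
                "ref": rec.ref,
                "alt": alt,
                "gene": ig(info, "GENE"),
                "func": ig(info, "FUNC"),
                "exonic_func": ig(info, "EXONIC_FUNC"),
                "sift": ig(info, "SIFT"),
                "polyphen": ig(info, "POLYPHEN"),
                "context": ig(info, "CONTEXT"),
                "kg_gold_indel": bool(ig(info, "KG_GOLD_INDEL", False)),
                "patient": ig(info, "PATIENT"),
            }
            for col, tag in amap.items():
                v = ig(info, tag)
                if isinstance(v, tuple):
                    v = v[0]
                base[col] = float(v) if v is not None else np.nan
            for name, call in rec.samples.items():
                ad = ig(call, "AD")
                if ad is None or ad[1] is None or ad[1] == 0:
                    continue
                row = dict(base)
                row["sample"] = name
                dp = ig(call, "DP")
                row["depth"] = dp if dp is not None else sum(x for x in ad if x is not None)
                row["alt_reads"] = ad[1]
                sac = ig(call, "SAC")
                if sac is not None and len(sac) >= 2:
                    row["plus_strand_alt"], row["minus_strand_alt"] = sac[0], sac[1]
                else:
                    row["plus_strand_alt"] = row["minus_strand_alt"] = np.nan
                rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        df = pd.DataFrame(columns=TSV_COLUMNS)
    if "patient" in df.columns and df["patient"].isna().all():
        df["patient"] = "unknown"
    for col in TSV_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    norm = [_normalize_indel(r, a, p) for r, a, p in zip(df["ref"], df["alt"], df["pos"])]
    df["ref"] = [x[0] for x in norm]
    df["alt"] = [x[1] for x in norm]
    df["pos"] = [x[2] for x in norm]
    return df


def write_variants_tsv(records: pd.DataFrame, path) -> None:
    cols = [c for c in TSV_COLUMNS + OPTIONAL_COLUMNS if c in records.columns]
    out = records[cols].copy()
    if "kg_gold_indel" in out.columns:
        out["kg_gold_indel"] = out["kg_gold_indel"].astype(int)
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
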