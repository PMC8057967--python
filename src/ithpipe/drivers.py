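"""Putative driver flagging against a curated gene list.

A passing variant is a putative driver if its gene is on the curated
list and it is either (1) a truncating event - nonsense/stopgain,
splicing (by functional region, per ANNOVAR convention) or frameshift
insertion/deletion - or (2) a missense change predicted deleterious by
at least one of SIFT and PolyPhen.  Start-loss and stop-loss variants
are not counted as nonsense.  Deleteriousness predictions are consumed
as annotations, never recomputed; the bundled example gene list is a
placeholder users replace with their own curated set (the analysis
this mirrors used a 573-gene list).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

TRUNCATING_FUNCS = {
    "stopgain",
    "nonsense",
    "frameshift insertion",
    "frameshift deletion",
    "frameshift_insertion",
    "frameshift_deletion",
}
MISSENSE_FUNCS = {"nonsynonymous snv", "nonsynonymous_snv", "nonsynonymous", "missense"}

_EXAMPLE_RESOURCE = "driver_genes_example.txt"


@dataclass
class DriverGeneList:
    genes: frozenset[str]
    source: str = "user"

    def __post_init__(self) -> None:
        self.genes = frozenset(g.strip().upper() for g in self.genes if g.strip())
        if not self.genes:
            raise ValueError("driver gene list is empty")

    @classmethod
    def from_file(cls, path) -> "DriverGeneList":
        with open(path) as fh:
            genes = [line.strip() for line in fh if line.strip() and not line.startswith("#")]
        return cls(genes=frozenset(genes), source=str(path))

    @classmethod
    def example(cls) -> "DriverGeneList":
        """Bundled example list (well-known cancer genes; replace in real use)."""
        ref = resources.files("ithpipe.data").joinpath(_EXAMPLE_RESOURCE)
        genes = [
            line.strip()
            for line in ref.read_text().splitlines()
            if line.strip() and not line.startswith("#")
        ]
        return cls(genes=frozenset(genes), source="bundled example")


def _norm(series: pd.Series) -> pd.Series:
    return series.astype(str).str.strip().str.lower()


def flag_drivers(records: pd.DataFrame, genes: DriverGeneList) -> pd.DataFrame:
    """Return `records` with a boolean ``driver`` column.

    Decisions are record-local.  Missense records lacking both SIFT and
    PolyPhen predictions are never flagged; a warning reports how many
    were skipped for missing annotations.
    """
    df = records.copy()
    gene_in = df["gene"].astype(str).str.upper().isin(genes.genes)
    ef = _norm(df.get("exonic_func", pd.Series("", index=df.index)))
    func = _norm(df.get("func", pd.Series("", index=df.index)))
    truncating = ef.isin(TRUNCATING_FUNCS) | func.eq("splicing")
    missense = ef.isin(MISSENSE_FUNCS)
    sift = _norm(df.get("sift", pd.Series("", index=df.index)))
    poly = _norm(df.get("polyphen", pd.Series("", index=df.index)))
    has_pred = sift.isin(["deleterious", "tolerated"]) | poly.isin(
        ["deleterious", "tolerated", "benign", "possibly_damaging", "probably_damaging"]
    )
    deleterious = sift.eq("deleterious") | poly.isin(
        ["deleterious", "probably_damaging", "possibly_damaging"]
    )
    skipped = int((gene_in & missense & ~has_pred).sum())
    if skipped:
        warnings.warn(
            f"{skipped} missense record(s) in listed genes lack SIFT/PolyPhen "
            "annotations and were not flagged",
            stacklevel=2,
        )
    df["driver"] = (gene_in & (truncating | (missense & deleterious))).to_numpy()
    return df


@dataclass
class DriverGrid:
    """Gene x sample occurrence grid with per-mutation truncal flags."""

    table: pd.DataFrame  # tidy: gene, mutation, sample, exonic_func, label, truncal
    grid: pd.DataFrame  # genes x samples, cell = ';'-joined mutation types


def driver_matrix(flagged: pd.DataFrame, labels: dict[str, str] | pd.Series) -> DriverGrid:
    """Build the driver heat-map grid from flagged records and phylo labels.

    `labels` maps mutation keys (``chrom:pos:ref>alt``) to
    trunk/shared/private.  A gene hit by two distinct variants in one
    sample records both types in the cell.
    """
    from .phylo_ith import mutation_key

    labels = dict(labels)
    hits = flagged[flagged["driver"]].copy()
    if hits.empty:
        return DriverGrid(
            table=pd.DataFrame(
                columns=["gene", "mutation", "sample", "exonic_func", "label", "truncal"]
            ),
            grid=pd.DataFrame(),
        )
    hits["mutation"] = [
        mutation_key(c, p, r, a)
        for c, p, r, a in zip(hits["chrom"], hits["pos"], hits["ref"], hits["alt"])
    ]
    hits["label"] = hits["mutation"].map(labels)
    missing = hits["label"].isna()
    if missing.any():
        raise ValueError(
            f"no trunk/shared/private label for mutation(s): "
            f"{sorted(hits.loc[missing, 'mutation'])[:5]}"
        )
    tidy = hits[["gene", "mutation", "sample", "exonic_func", "label"]].copy()
    tidy["truncal"] = np.where(tidy["label"] == "trunk", True, False)
    tidy = tidy.sort_values(["gene", "mutation", "sample"]).reset_index(drop=True)
    grid = (
        tidy.groupby(["gene", "sample"])["exonic_func"]
        .apply(lambda s: ";".join(sorted(map(str, s))))
        .unstack(fill_value="")
        .sort_index()
    )
    return DriverGrid(table=tidy, grid=grid)
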