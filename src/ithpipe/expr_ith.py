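"""Transcriptional heterogeneity: RPKM, variable genes, two-group
clustering, differential expression, set enrichment and the HLA/CIITA
association.

Within each patient, raw gene counts are normalised to RPKM
(count * 1e9 / (gene length * library size)); genes with mean
log2(RPKM+1) below 1 are dropped, the most variable genes are kept by
median absolute deviation of log2(RPKM+1) (default cutoff 1), samples
are split into two groups at the top of an average-linkage
correlation-distance dendrogram, and differentially expressed genes
(DEGs) are those with a between-group mean-RPKM fold change >= 2 or
<= 0.5.  Enrichment of DEGs in user-supplied gene sets uses the
one-sided hypergeometric tail with Benjamini-Hochberg adjustment.

The HLA analysis pools all region-samples across patients: expression
of a fixed panel of 9 MHC class I and 16 MHC class II genes is
examined, and each class II gene is regressed (ordinary least squares
in log2(RPKM+1) space) on the class II transactivator CIITA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

MHC_CLASS_I = (
    "HLA-A", "HLA-B", "HLA-C", "HLA-E", "HLA-F", "HLA-H", "HLA-G", "HLA-J", "HLA-L",
)
MHC_CLASS_II = (
    "CD74", "HLA-DMA", "HLA-DMB", "HLA-DOA", "HLA-DOB",
    "HLA-DPA1", "HLA-DPB1", "HLA-DPB2", "HLA-DQA1", "HLA-DQA2",
    "HLA-DQB1", "HLA-DQB2", "HLA-DRA", "HLA-DRB1", "HLA-DRB5", "HLA-DRB6",
)


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance values with gene lengths.

    ``value_kind`` is ``"counts"`` (raw integers; lengths required for
    RPKM) or ``"rpkm"`` (already normalised).
    """

    values: pd.DataFrame
    lengths: pd.Series | None = None
    value_kind: str = "counts"
    patient_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.value_kind == "counts":
            if self.lengths is None:
                raise ValueError("gene lengths required for count matrices")
            self.lengths = self.lengths.reindex(self.values.index)
            if self.lengths.isna().any() or (self.lengths <= 0).any():
                raise ValueError("every gene needs a positive length")
        elif self.value_kind != "rpkm":
            raise ValueError(f"unknown value_kind {self.value_kind!r}")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_of_patient(self, patient: str) -> list[str]:
        return [s for s in self.samples if self.patient_of.get(s) == patient]


def rpkm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Reads per kilobase per million mapped reads.

    value = count * 1e9 / (length_bases * library_size), with library
    size the per-sample column sum.  A matrix already in RPKM is
    returned unchanged.
    """
    if matrix.value_kind == "rpkm":
        return matrix
    counts = matrix.values
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        raise ValueError(f"zero library size for sample(s) {list(lib.index[lib == 0])}")
    vals = counts.mul(1e9).div(matrix.lengths, axis=0).div(lib, axis=1)
    return ExpressionMatrix(
        values=vals, lengths=matrix.lengths, value_kind="rpkm", patient_of=dict(matrix.patient_of)
    )


def log2p1(values: pd.DataFrame) -> pd.DataFrame:
    """log2(x + 1); the pseudocount keeps zeros finite."""
    return np.log2(values + 1.0)


def select_variable_genes(
    rpkm_values: pd.DataFrame, min_mean_log2: float = 1.0, min_mad_log2: float = 1.0
) -> pd.DataFrame:
    """Drop lowly expressed then low-variability genes (order preserved).

    A gene is kept when its mean log2(RPKM+1) across samples is >=
    `min_mean_log2` and the (unscaled) median absolute deviation of
    log2(RPKM+1) is >= `min_mad_log2`.
    """
    lg = log2p1(rpkm_values)
    keep_mean = lg.mean(axis=1) >= min_mean_log2
    mad = (lg.sub(lg.median(axis=1), axis=0)).abs().median(axis=1)
    keep = keep_mean & (mad >= min_mad_log2)
    return rpkm_values.loc[keep]


def cluster_two_groups(
    rpkm_values: pd.DataFrame,
    metric: str = "correlation",
    linkage_method: str = "average",
) -> tuple[pd.Series, np.ndarray]:
    """Split samples into two groups at the top of a hierarchical tree.

    Distance between samples defaults to 1 - Pearson correlation over
    the supplied (variable) genes, with average linkage; the
    bipartition is the two children of the final merge.  Returns
    (sample -> group label in {0, 1}, linkage matrix).
    """
    samples = list(rpkm_values.columns)
    if len(samples) < 2:
        raise ValueError("clustering needs >=2 samples")
    lg = log2p1(rpkm_values).to_numpy().T  # samples x genes
    if len(samples) == 2:
        return pd.Series([0, 1], index=samples), np.array([[0.0, 1.0, 1.0, 2.0]])
    if metric == "correlation":
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(lg)
        corr = np.nan_to_num(corr, nan=0.0)
        dist = 1.0 - corr
        np.fill_diagonal(dist, 0.0)
        dist = np.maximum(dist, dist.T)
        condensed = squareform(dist, checks=False)
    else:
        from scipy.spatial.distance import pdist

        condensed = pdist(lg, metric=metric)
    Z = hierarchy.linkage(condensed, method=linkage_method)
    groups = hierarchy.fcluster(Z, t=2, criterion="maxclust") - 1
    return pd.Series(groups, index=samples), Z


@dataclass
class DegSet:
    """DEGs between the two clustered groups of one patient."""

    genes: list[str]
    fold_change: pd.Series  # (mean A + eps)/(mean B + eps), all tested genes
    direction: pd.Series  # 'up' (FC >= 2) or 'down' (FC <= 0.5), DEGs only
    groups: pd.Series  # sample -> 0/1

    @property
    def n(self) -> int:
        return len(self.genes)


def identify_degs(
    rpkm_values: pd.DataFrame,
    groups: pd.Series,
    fc_high: float = 2.0,
    fc_low: float = 0.5,
    eps: float = 0.01,
) -> DegSet:
    """Fold-change DEGs between the two groups (boundaries included).

    FC = (mean RPKM in group 0 + eps) / (mean RPKM in group 1 + eps);
    `eps` guards division by zero.  Both group sides must be nonempty.
    """
    g0 = [s for s in rpkm_values.columns if groups[s] == 0]
    g1 = [s for s in rpkm_values.columns if groups[s] == 1]
    if not g0 or not g1:
        raise ValueError("both groups must be nonempty")
    fc = (rpkm_values[g0].mean(axis=1) + eps) / (rpkm_values[g1].mean(axis=1) + eps)
    is_deg = (fc >= fc_high) | (fc <= fc_low)
    direction = pd.Series(
        np.where(fc[is_deg] >= fc_high, "up", "down"), index=fc.index[is_deg]
    )
    return DegSet(
        genes=list(fc.index[is_deg]), fold_change=fc, direction=direction, groups=groups
    )


def read_gmt(path) -> dict[str, list[str]]:
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, name] + list(genes)) + "\n")


def enrich(
    deg_genes, universe, gene_sets: dict[str, list[str]]
) -> pd.DataFrame:
    """Hypergeometric over-representation of DEGs in each gene set.

    p = P(X >= k) with k the overlap, drawing |DEG| genes from a
    universe containing |set ∩ universe| successes; Benjamini-Hochberg
    adjusted across sets.
    """
    universe = set(universe)
    degs = set(deg_genes) & universe
    if set(deg_genes) - universe:
        raise ValueError("DEG genes must be contained in the universe")
    rows = []
    for name, members in gene_sets.items():
        m = set(members) & universe
        if not m:
            continue
        k = len(degs & m)
        p = float(stats.hypergeom.sf(k - 1, len(universe), len(m), len(degs)))
        rows.append({"set": name, "set_size": len(m), "overlap": k, "pvalue": p})
    frame = pd.DataFrame(rows)
    if frame.empty:
        return pd.DataFrame(columns=["set", "set_size", "overlap", "pvalue", "padj"])
    frame["padj"] = multipletests(frame["pvalue"], method="fdr_bh")[1]
    return frame.sort_values(["pvalue", "set"]).reset_index(drop=True)


@dataclass
class HlaPanel:
    """Fixed HLA gene panel (overridable from file): 9 class I, 16 class II."""

    class_i: tuple[str, ...] = MHC_CLASS_I
    class_ii: tuple[str, ...] = MHC_CLASS_II
    regulator: str = "CIITA"

    @classmethod
    def from_file(cls, path, regulator: str = "CIITA") -> "HlaPanel":
        tab = pd.read_csv(path, sep="\t")
        return cls(
            class_i=tuple(tab.loc[tab["class"] == "I", "gene"]),
            class_ii=tuple(tab.loc[tab["class"] == "II", "gene"]),
            regulator=regulator,
        )

    @property
    def genes(self) -> tuple[str, ...]:
        return self.class_i + self.class_ii


def hla_submatrix(rpkm_values: pd.DataFrame, panel: HlaPanel | None = None) -> pd.DataFrame:
    panel = panel or HlaPanel()
    present = [g for g in panel.genes if g in rpkm_values.index]
    return rpkm_values.loc[present]


def hla_association(
    rpkm_values: pd.DataFrame,
    panel: HlaPanel | None = None,
    targets: list[str] | None = None,
) -> pd.DataFrame:
    """OLS fit of each class II gene on the regulator across all samples.

    Fits target = slope * regulator + intercept in log2(RPKM+1) space,
    pooling every region-sample; returns slope, intercept, Pearson r
    and R^2 per target, ranked by R^2.  A zero-variance regulator is
    flagged (all-NaN fits) rather than raising.
    """
    panel = panel or HlaPanel()
    if panel.regulator not in rpkm_values.index:
        raise ValueError(f"regulator {panel.regulator!r} not in expression matrix")
    targets = list(targets) if targets is not None else [
        g for g in panel.class_ii if g in rpkm_values.index
    ]
    lg = log2p1(rpkm_values)
    x = lg.loc[panel.regulator].to_numpy()
    rows = []
    degenerate = np.allclose(x, x[0])
    if degenerate:
        warnings.warn("regulator expression is constant; fits undefined", stacklevel=2)
    for t in targets:
        y = lg.loc[t].to_numpy()
        if degenerate:
            rows.append(
                {"target": t, "slope": np.nan, "intercept": np.nan, "r": np.nan, "r2": np.nan}
            )
            continue
        fit = stats.linregress(x, y)
        rows.append(
            {
                "target": t,
                "slope": float(fit.slope),
                "intercept": float(fit.intercept),
                "r": float(fit.rvalue),
                "r2": float(fit.rvalue**2),
            }
        )
    frame = pd.DataFrame(rows)
    if not degenerate and not frame.empty:
        frame = frame.sort_values("r2", ascending=False).reset_index(drop=True)
    return frame


def zscore_rows(values: pd.DataFrame) -> pd.DataFrame:
    """Scale each gene to mean 0 and sd 1 across samples (heat-map export)."""
    lg = log2p1(values)
    sd = lg.std(axis=1, ddof=0).replace(0, 1.0)
    return lg.sub(lg.mean(axis=1), axis=0).div(sd, axis=0)


def read_counts_tsv(path, lengths_path=None) -> ExpressionMatrix:
    """Read a genes x samples counts TSV.

    The first column is the gene id; a ``length`` column (or separate
    two-column lengths TSV) supplies gene lengths in bases.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "length" in df.columns:
        lengths = df["length"]
        df = df.drop(columns=["length"])
    elif lengths_path is not None:
        lt = pd.read_csv(lengths_path, sep="\t", index_col=0)
        lengths = lt.iloc[:, 0]
    else:
        raise ValueError("counts TSV needs a 'length' column or a lengths file")
    return ExpressionMatrix(values=df, lengths=lengths, value_kind="counts")


def write_counts_tsv(matrix: ExpressionMatrix, path) -> None:
    out = matrix.values.copy()
    if matrix.lengths is not None:
        out.insert(0, "length", matrix.lengths)
    out.to_csv(path, sep="\t", float_format="%.8g")
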