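"""Synthetic multi-region tumor cohorts with known ground truth.

The generator emulates the study design the pipeline targets: a cohort
of patients, each sampled in 3-9 spatially distinct tumor regions
cultured as high-purity cell lines.  Somatic mutations are placed on a
random bifurcating clonal tree - trunk mutations on the root edge
(present in every region), shared mutations on internal edges (present
in a clade of at least two but not all regions), private mutations on
terminal edges - and each present call carries Poisson depth, binomial
alt-read and per-strand counts, a trinucleotide context drawn from a
class-specific signature mixture, and population-AF annotations (zero
for somatic calls, elevated for planted germline contaminants).
Copy-number events are planted on whole cytobands with a configurable
fraction of affected regions, and expression matrices carry a planted
two-subgroup structure plus an HLA class II module linearly driven by
a regulator gene (CIITA).

Every stochastic choice flows from a single integer seed, so identical
configurations produce byte-identical outputs.  Gene-level expression
parameters (baselines, lengths, fold directions) depend on the seed
only - not the patient - so per-patient matrices concatenate into a
coherent cohort matrix for the pooled HLA association.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import mutsig
from .expr_ith import MHC_CLASS_I, MHC_CLASS_II, ExpressionMatrix
from .mutsig import CONTEXT_96, SpectrumProfile
from .variant_filter import TSV_COLUMNS, write_variants_tsv

AUTOSOMES = [str(i) for i in range(1, 23)]

# rough chromosome lengths (bases); a simplified karyotype for simulation
CHROM_LENGTHS = {
    "1": 249_000_000, "2": 243_000_000, "3": 198_000_000, "4": 191_000_000,
    "5": 181_000_000, "6": 171_000_000, "7": 159_000_000, "8": 146_000_000,
    "9": 141_000_000, "10": 136_000_000, "11": 135_000_000, "12": 134_000_000,
    "13": 115_000_000, "14": 107_000_000, "15": 103_000_000, "16": 90_000_000,
    "17": 81_000_000, "18": 78_000_000, "19": 59_000_000, "20": 63_000_000,
    "21": 48_000_000, "22": 51_000_000, "X": 155_000_000, "Y": 59_000_000,
}

_P_BANDS = ["p15", "p14", "p13", "p12", "p11"]
_Q_BANDS = ["q11", "q12", "q13", "q14", "q21", "q22", "q23", "q24", "q25"]


def default_cytobands() -> pd.DataFrame:
    """A deterministic simplified cytoband table for the synthetic genome.

    Each chromosome carries five p and nine q bands of equal width
    within each arm (p arm = 40% of the chromosome).  1-based inclusive
    coordinates, ids like ``9p13``.
    """
    rows = []
    for chrom, length in CHROM_LENGTHS.items():
        p_len = int(length * 0.4)
        bw = p_len // len(_P_BANDS)
        pos = 1
        for b in _P_BANDS:
            end = pos + bw - 1
            rows.append((f"{chrom}{b}", chrom, pos, end))
            pos = end + 1
        q_bw = (length - pos + 1) // len(_Q_BANDS)
        for i, b in enumerate(_Q_BANDS):
            end = length if i == len(_Q_BANDS) - 1 else pos + q_bw - 1
            rows.append((f"{chrom}{b}", chrom, pos, end))
            pos = end + 1
    return pd.DataFrame(rows, columns=["cytoband", "chrom", "start", "end"])


def write_cytobands(bands: pd.DataFrame, path) -> None:
    """Write a UCSC-style cytoBand file (0-based half-open, chr-prefixed)."""
    out = pd.DataFrame(
        {
            "chrom": "chr" + bands["chrom"].astype(str),
            "start0": bands["start"] - 1,
            "end": bands["end"],
            "band": [cb[len(c):] for cb, c in zip(bands["cytoband"], bands["chrom"].astype(str))],
            "stain": "gneg",
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the target design: seven patients with 3-9 regions
    each, roughly 160 somatic mutations per patient of which ~26% are
    silent, mean sequencing depth 136, clonal variant allele fractions
    at purity 1, trunk spectra dominated by Signature 1 and branch
    spectra drawn from a more complex mixture.
    """

    n_patients: int = 7
    regions_per_patient: int | tuple[int, int] = (3, 9)
    n_trunk: int = 97
    n_shared: int = 30
    n_private: int = 30
    silent_fraction: float = 0.265
    indel_fraction: float = 0.08
    n_driver_mutations: int = 2
    driver_genes: tuple[str, ...] = ("TP53", "KMT2C", "CDKN2A", "ARID1A", "ARID1B", "ERBB2")
    mean_depth: float = 136.0
    vaf_trunk: float = 0.5
    vaf_branch: float = 0.4
    purity: float = 1.0
    strand_bias_outlier_rate: float = 0.01
    contaminant_rate: float = 0.02
    homoplasy_rate: float = 0.0
    signature_mix_trunk: dict[str, float] = field(
        default_factory=lambda: {"Signature 1": 0.8, "Signature 4": 0.2}
    )
    signature_mix_branch: dict[str, float] = field(
        default_factory=lambda: {
            "Signature 1": 0.3,
            "Signature 6": 0.35,
            "Signature 15": 0.2,
            "Signature 4": 0.15,
        }
    )
    cnv_events: tuple = (
        ("9p13", "loss", 1.0),
        ("11q13", "gain", 1.0),
        ("5p15", "gain", 1.0),
        ("8q24", "gain", 0.6),
        ("1p11", "loss", 0.5),
    )
    cnv_log2_gain: float = 0.6
    cnv_log2_loss: float = -0.6
    cnv_noise_sd: float = 0.05
    expr_background: int = 500
    expr_deg: int = 100
    deg_fold: float = 2.5
    expr_noise_sd: float = 0.1
    expr_subgroup_split: int | None = None  # size of group 0; None = balanced
    expr_value_kind: str = "counts"
    hla_regulator_slope: float = 1.0
    hla_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.region_bounds()
        if not (3 <= lo <= hi <= 9):
            raise ValueError("regions_per_patient must lie within [3, 9]")
        for name in ("vaf_trunk", "vaf_branch"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")
        for name in ("signature_mix_trunk", "signature_mix_branch"):
            mix = getattr(self, name)
            if not mix:
                raise ValueError(f"{name} must be a nonempty mixture")
            if abs(sum(mix.values()) - 1.0) > 1e-9 or any(w < 0 for w in mix.values()):
                raise ValueError(f"{name} weights must be non-negative and sum to 1")
        if self.n_trunk + self.n_shared + self.n_private < 1:
            raise ValueError("at least one mutation per patient required")
        if self.expr_value_kind not in ("counts", "rpkm"):
            raise ValueError("expr_value_kind must be 'counts' or 'rpkm'")

    def region_bounds(self) -> tuple[int, int]:
        if isinstance(self.regions_per_patient, int):
            return self.regions_per_patient, self.regions_per_patient
        lo, hi = self.regions_per_patient
        return int(lo), int(hi)


@dataclass
class GroundTruth:
    """Generating truth for one simulated patient."""

    patient_id: str
    sample_ids: list[str]
    labels: dict[str, str]  # mutation key -> trunk|shared|private
    presence: dict[str, list[str]]  # mutation key -> carrying samples
    silent: dict[str, bool]
    tree_newick: str
    signature_mixes: dict[str, dict[str, float]]
    cnv: dict[str, dict]
    contaminants: list[str]
    deg_genes: dict[str, str]  # gene -> up|down (relative to group 0)
    expr_groups: dict[str, int]
    regulator_pairs: list[tuple[str, str, float]]
    driver_mutations: list[str]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        d["regulator_pairs"] = [tuple(p) for p in d["regulator_pairs"]]
        return cls(**d)


def _patient_rng(seed: int, patient_id: str, stream: int = 0) -> np.random.Generator:
    return np.random.default_rng((seed, zlib.crc32(patient_id.encode()), stream))


def _random_tree(n: int, rng: np.random.Generator):
    """Random bifurcating topology over leaves 0..n-1 (nested tuples)."""
    order = [int(x) for x in rng.permutation(n)]
    tree = (order[0], order[1]) if n > 1 else order[0]
    for leaf in order[2:]:
        edges = _count_nodes(tree)
        k = int(rng.integers(edges))
        tree, _ = _insert_at(tree, int(leaf), k)
    return tree


def _count_nodes(tree) -> int:
    if isinstance(tree, int):
        return 1
    return 1 + _count_nodes(tree[0]) + _count_nodes(tree[1])


def _insert_at(tree, leaf: int, k: int):
    """Insert `leaf` above the k-th node in preorder; returns (tree, consumed)."""
    if k == 0:
        return (tree, leaf), -1
    if isinstance(tree, int):
        return tree, k - 1
    left, right = tree
    new_left, k = _insert_at(left, leaf, k - 1)
    if k < 0:
        return (new_left, right), -1
    new_right, k = _insert_at(right, leaf, k)
    if k < 0:
        return (left, new_right), -1
    return tree, k


def _clades(tree, n: int) -> list[frozenset]:
    """Internal clades usable for shared mutations (2 <= size < n)."""
    out = []

    def rec(node) -> frozenset:
        if isinstance(node, int):
            return frozenset([node])
        c = rec(node[0]) | rec(node[1])
        if 2 <= len(c) < n:
            out.append(c)
        return c

    rec(tree)
    return out


def _tree_newick(tree, sample_ids: list[str]) -> str:
    def rec(node) -> str:
        if isinstance(node, int):
            return sample_ids[node]
        return f"({rec(node[0])},{rec(node[1])})"

    return rec(tree) + ";"


def _context_fields(category: str) -> tuple[str, str, str]:
    """(ref, alt, context label) from a 96-category label."""
    return category[2], category[4], category


# ---------------------------------------------------------------------------
# Mutation tables


def simulate_patient(
    cfg: SimConfig,
    patient_id: str,
    reference: pd.DataFrame | None = None,
    cytobands: pd.DataFrame | None = None,
):
    """Simulate one patient's variant table, expression, CNV segments and truth.

    Returns ``(variants, expression, segments, truth)``.  Deterministic
    for a fixed ``(cfg, patient_id)``.
    """
    reference = reference if reference is not None else mutsig.load_signature_matrix()
    cytobands = cytobands if cytobands is not None else default_cytobands()
    rng = _patient_rng(cfg.seed, patient_id, stream=1)
    lo, hi = cfg.region_bounds()
    n_regions = int(rng.integers(lo, hi + 1))
    samples = [f"{patient_id}_R{i + 1}" for i in range(n_regions)]

    tree = _random_tree(n_regions, rng)
    shared_clades = _clades(tree, n_regions)

    trunk_probs = mutsig.mixture_distribution(cfg.signature_mix_trunk, reference)
    branch_probs = mutsig.mixture_distribution(cfg.signature_mix_branch, reference)

    # --- mutation specifications -------------------------------------------
    specs = []  # (class, carrier set, is_driver)
    all_set = frozenset(range(n_regions))
    for _ in range(cfg.n_trunk):
        specs.append(("trunk", all_set, False))
    for _ in range(cfg.n_shared):
        if cfg.homoplasy_rate > 0 and rng.random() < cfg.homoplasy_rate:
            size = int(rng.integers(2, n_regions))
            carriers = frozenset(rng.choice(n_regions, size=size, replace=False).tolist())
        else:
            carriers = shared_clades[int(rng.integers(len(shared_clades)))]
        specs.append(("shared", carriers, False))
    for _ in range(cfg.n_private):
        specs.append(("private", frozenset([int(rng.integers(n_regions))]), False))
    driver_genes = list(rng.choice(
        cfg.driver_genes, size=min(cfg.n_driver_mutations, len(cfg.driver_genes)), replace=False
    ))
    for _ in driver_genes:
        specs.append(("trunk", all_set, True))
    n_somatic = len(specs)
    n_cont = int(round(cfg.contaminant_rate * n_somatic))

    # unique genomic positions
    chrom_p = np.array([CHROM_LENGTHS[c] for c in AUTOSOMES], dtype=float)
    chrom_p /= chrom_p.sum()
    seen: set[tuple[str, int]] = set()

    def draw_site() -> tuple[str, int]:
        while True:
            chrom = AUTOSOMES[int(rng.choice(len(AUTOSOMES), p=chrom_p))]
            pos = int(rng.integers(1_000_000, CHROM_LENGTHS[chrom] - 1_000_000))
            if (chrom, pos) not in seen:
                seen.add((chrom, pos))
                return chrom, pos

    rows = []
    labels: dict[str, str] = {}
    presence: dict[str, list[str]] = {}
    silent_map: dict[str, bool] = {}
    driver_keys: list[str] = []
    contaminant_keys: list[str] = []
    gene_counter = 0
    driver_iter = iter(driver_genes)

    def emit_records(key, chrom, pos, ref, alt, context, gene, func, exonic_func,
                     sift, polyphen, carriers, vaf, pop_afs, gold=False):
        for ridx in sorted(carriers):
            depth = max(int(rng.poisson(cfg.mean_depth)), 1)
            p_alt = min(max(vaf * cfg.purity, 1e-6), 1.0)
            alt_reads = max(int(rng.binomial(depth, p_alt)), 1)
            if rng.random() < cfg.strand_bias_outlier_rate:
                plus = int(np.ceil(0.95 * alt_reads))
            else:
                plus = int(rng.binomial(alt_reads, 0.5))
            rows.append(
                {
                    "patient": patient_id,
                    "sample": samples[ridx],
                    "chrom": chrom,
                    "pos": pos,
                    "ref": ref,
                    "alt": alt,
                    "depth": depth,
                    "alt_reads": alt_reads,
                    "plus_strand_alt": plus,
                    "minus_strand_alt": alt_reads - plus,
                    "gene": gene,
                    "func": func,
                    "exonic_func": exonic_func,
                    "dbsnp_af": pop_afs[0],
                    "converge_af": pop_afs[1],
                    "kg_af": pop_afs[2],
                    "esp_af": pop_afs[3],
                    "exac_af": pop_afs[4],
                    "sift": sift,
                    "polyphen": polyphen,
                    "context": context,
                    "kg_gold_indel": gold,
                }
            )

    for cls, carriers, is_driver in specs:
        chrom, pos = draw_site()
        probs = trunk_probs if cls == "trunk" else branch_probs
        is_indel = (not is_driver) and rng.random() < cfg.indel_fraction
        if is_indel:
            anchor = "ACGT"[int(rng.integers(4))]
            ins = "".join("ACGT"[int(b)] for b in rng.integers(0, 4, size=int(rng.integers(1, 4))))
            if rng.random() < 0.5:
                ref, alt = anchor, anchor + ins
                exonic_func = "frameshift insertion" if len(ins) % 3 else "nonframeshift insertion"
            else:
                ref, alt = anchor + ins, anchor
                exonic_func = "frameshift deletion" if len(ins) % 3 else "nonframeshift deletion"
            context, sift, polyphen = np.nan, np.nan, np.nan
            silent = False
        else:
            cat = CONTEXT_96[int(rng.choice(96, p=probs))]
            ref, alt, context = _context_fields(cat)
            if is_driver:
                exonic_func, silent = "stopgain", False
                sift, polyphen = "deleterious", "deleterious"
            else:
                silent = rng.random() < cfg.silent_fraction
                exonic_func = "synonymous SNV" if silent else "nonsynonymous SNV"
                if silent:
                    sift, polyphen = np.nan, np.nan
                else:
                    sift = "deleterious" if rng.random() < 0.35 else "tolerated"
                    polyphen = "deleterious" if rng.random() < 0.35 else "benign"
        if is_driver:
            gene = next(driver_iter)
        else:
            gene_counter += 1
            gene = f"GENE{gene_counter:04d}"
        key = f"{chrom}:{pos}:{ref}>{alt}"
        vaf = cfg.vaf_trunk if cls == "trunk" else cfg.vaf_branch
        emit_records(
            key, chrom, pos, ref, alt, context, gene, "exonic", exonic_func,
            sift, polyphen, carriers, vaf, (0.0,) * 5,
        )
        labels[key] = cls
        presence[key] = [samples[i] for i in sorted(carriers)]
        silent_map[key] = silent
        if is_driver:
            driver_keys.append(key)

    for _ in range(n_cont):
        chrom, pos = draw_site()
        cat = CONTEXT_96[int(rng.choice(96, p=trunk_probs))]
        ref, alt, context = _context_fields(cat)
        gene_counter += 1
        afs = tuple(float(rng.uniform(0.02, 0.3)) for _ in range(5))
        key = f"{chrom}:{pos}:{ref}>{alt}"
        emit_records(
            key, chrom, pos, ref, alt, context, f"GENE{gene_counter:04d}", "exonic",
            "nonsynonymous SNV", "tolerated", "benign", all_set, 0.5, afs,
        )
        contaminant_keys.append(key)

    variants = pd.DataFrame(rows, columns=TSV_COLUMNS + ["context", "kg_gold_indel"])
    variants = variants.sort_values(["chrom", "pos", "sample"], kind="stable").reset_index(drop=True)

    segments = _simulate_cnv(cfg, samples, cytobands, rng)
    expression, expr_truth = simulate_expression(cfg, samples, patient_id=patient_id)

    cnv_truth = {}
    for band, direction, frac in cfg.cnv_events:
        n_aff = int(np.ceil(frac * n_regions))
        cnv_truth[band] = {
            "direction": direction,
            "n_affected": n_aff,
            "n_regions": n_regions,
            "ubiquity": "ubiquitous" if n_aff == n_regions else "heterogeneous",
        }

    truth = GroundTruth(
        patient_id=patient_id,
        sample_ids=samples,
        labels=labels,
        presence=presence,
        silent=silent_map,
        tree_newick=_tree_newick(tree, samples),
        signature_mixes={
            "trunk": dict(cfg.signature_mix_trunk),
            "branch": dict(cfg.signature_mix_branch),
        },
        cnv=cnv_truth,
        contaminants=contaminant_keys,
        deg_genes=expr_truth["deg_genes"],
        expr_groups=expr_truth["groups"],
        regulator_pairs=expr_truth["regulator_pairs"],
        driver_mutations=driver_keys,
    )
    return variants, expression, segments, truth


def _simulate_cnv(cfg, samples, cytobands, rng) -> pd.DataFrame:
    """Per-sample SEG partition: background plus planted band events."""
    n = len(samples)
    band_lookup = cytobands.set_index("cytoband")
    affected: dict[str, set[int]] = {}
    for band, direction, frac in cfg.cnv_events:
        if band not in band_lookup.index:
            raise ValueError(f"cnv event band {band!r} not in cytoband table")
        n_aff = int(np.ceil(frac * n))
        order = rng.permutation(n)
        affected[band] = set(int(i) for i in order[:n_aff])
    rows = []
    for sidx, sample in enumerate(samples):
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for band, direction, frac in cfg.cnv_events:
            if sidx not in affected[band]:
                continue
            info = band_lookup.loc[band]
            level = cfg.cnv_log2_gain if direction == "gain" else cfg.cnv_log2_loss
            per_chrom.setdefault(str(info["chrom"]), []).append(
                (int(info["start"]), int(info["end"]), level + float(rng.normal(0, cfg.cnv_noise_sd)))
            )
        for chrom in AUTOSOMES + ["X", "Y"]:
            length = CHROM_LENGTHS[chrom]
            events = sorted(per_chrom.get(chrom, []))
            pos = 1
            for start, end, level in events:
                if start > pos:
                    rows.append((sample, chrom, pos, start - 1, float(rng.normal(0, cfg.cnv_noise_sd))))
                rows.append((sample, chrom, start, end, level))
                pos = end + 1
            if pos <= length:
                rows.append((sample, chrom, pos, length, float(rng.normal(0, cfg.cnv_noise_sd))))
    return pd.DataFrame(rows, columns=["sample_id", "chrom", "start", "end", "log2"])


# ---------------------------------------------------------------------------
# Expression


def _gene_params(cfg: SimConfig) -> pd.DataFrame:
    """Cohort-level gene parameters (seed-dependent, patient-independent)."""
    rng = np.random.default_rng((cfg.seed, 777))
    rows = []
    for i in range(cfg.expr_background):
        rows.append((f"BG{i + 1:04d}", "background", float(rng.normal(5.0, 1.2)), "none"))
    for i in range(cfg.expr_deg):
        direction = "up" if i % 2 == 0 else "down"
        rows.append((f"DEG{i + 1:04d}", "deg", float(rng.normal(5.0, 1.2)), direction))
    for g in MHC_CLASS_I:
        rows.append((g, "hla_i", float(rng.normal(8.0, 0.5)), "none"))
    for g in MHC_CLASS_II:
        rows.append((g, "hla_ii", float(rng.uniform(1.0, 3.0)), "none"))
    rows.append(("CIITA", "regulator", 4.0, "none"))
    frame = pd.DataFrame(rows, columns=["gene", "kind", "base", "direction"])
    frame["length"] = rng.integers(500, 5001, size=len(frame))
    return frame.set_index("gene")


def simulate_expression(
    cfg: SimConfig, sample_ids: list[str], patient_id: str | None = None
) -> tuple[ExpressionMatrix, dict]:
    """Simulate a genes x samples expression matrix for one patient.

    Samples are split into two subgroups; planted DEG genes shift by
    ``log2(deg_fold)`` in group 0 (up) or group 1 (down); class II HLA
    genes follow ``slope * regulator + intercept`` in log2 space with
    Gaussian noise; background genes are exchangeable across samples.
    With ``expr_value_kind="counts"`` integer counts are drawn
    (Poisson) so the RPKM computation is exercised downstream; with
    ``"rpkm"`` the log-space values are emitted exactly (no count
    rounding), which the noiseless-linearity contracts rely on.
    """
    n = len(sample_ids)
    if n < 2:
        raise ValueError("need >=2 samples")
    split = cfg.expr_subgroup_split if cfg.expr_subgroup_split is not None else n // 2
    if not (0 < split < n):
        raise ValueError("expr_subgroup_split must leave both groups nonempty")
    rng = _patient_rng(cfg.seed, patient_id or "|".join(sample_ids), stream=2)
    params = _gene_params(cfg)
    groups = {s: (0 if i < split else 1) for i, s in enumerate(sample_ids)}
    shift = np.log2(cfg.deg_fold)

    reg_level = 4.0 + 2.0 * rng.random(n)  # regulator log2 level per sample
    log2_vals = np.zeros((len(params), n))
    for j in range(n):
        g = 0 if groups[sample_ids[j]] == 0 else 1
        noise = rng.normal(0.0, cfg.expr_noise_sd, size=len(params))
        for i, (gene, row) in enumerate(params.iterrows()):
            x = row["base"]
            if row["kind"] == "deg":
                if (row["direction"] == "up") == (g == 0):
                    x += shift
            elif row["kind"] == "regulator":
                x = reg_level[j]
                noise[i] = 0.0
            elif row["kind"] == "hla_ii":
                x = cfg.hla_regulator_slope * reg_level[j] + row["base"]
                noise[i] = rng.normal(0.0, cfg.hla_noise_sd) if cfg.hla_noise_sd > 0 else 0.0
            log2_vals[i, j] = max(x + noise[i], 0.0)

    if cfg.expr_value_kind == "rpkm":
        values = pd.DataFrame(
            np.exp2(log2_vals) - 1.0, index=params.index, columns=sample_ids
        )
        matrix = ExpressionMatrix(
            values=values,
            lengths=params["length"],
            value_kind="rpkm",
            patient_of={s: patient_id or "sim" for s in sample_ids},
        )
    else:
        rates = np.exp2(log2_vals)
        counts = rng.poisson(rates)
        values = pd.DataFrame(counts, index=params.index, columns=sample_ids)
        matrix = ExpressionMatrix(
            values=values,
            lengths=params["length"],
            value_kind="counts",
            patient_of={s: patient_id or "sim" for s in sample_ids},
        )
    truth = {
        "deg_genes": {
            g: str(row["direction"]) for g, row in params.iterrows() if row["kind"] == "deg"
        },
        "groups": groups,
        "regulator_pairs": [
            ("CIITA", g, float(cfg.hla_regulator_slope))
            for g in params.index[params["kind"] == "hla_ii"]
        ],
    }
    return matrix, truth


# ---------------------------------------------------------------------------
# Spectra


def simulate_spectra(
    mix: dict[str, float],
    n: int,
    reference: pd.DataFrame,
    seed: int | np.random.Generator = 0,
    label: str = "simulated",
) -> SpectrumProfile:
    """Draw `n` trinucleotide contexts from a signature mixture.

    Returns a 96-category count profile summing to `n` (multinomial
    sampling from the mixture distribution).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    probs = mutsig.mixture_distribution(mix, reference)
    counts = rng.multinomial(n, probs)
    return SpectrumProfile(label=label, context96=counts.astype(np.int64))


# ---------------------------------------------------------------------------
# Planted-violation filter tables


def simulate_filter_table(
    n_records: int,
    violation_fraction: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """A variant table with per-criterion planted violations.

    Roughly `violation_fraction` of records violate exactly one filter
    criterion (uniformly chosen); the rest are clean.  Returns the
    table and the per-row truth (``"pass"`` or the expected rejection
    label), for filter-fidelity checks against an independent
    per-record oracle.
    """
    from .variant_filter import CRITERIA

    rng = np.random.default_rng(seed)
    rows, truth = [], []
    for i in range(n_records):
        chrom = AUTOSOMES[int(rng.integers(22))]
        pos = int(rng.integers(1_000_000, 100_000_000))
        depth = int(rng.integers(60, 200))
        alt = int(rng.integers(max(8, int(0.1 * depth) + 1), depth // 2 + 1))
        plus = int(rng.binomial(alt, 0.5))
        plus = min(max(plus, int(np.ceil(0.15 * alt))), alt - max(1, int(np.ceil(0.15 * alt))))
        rec = {
            "patient": "SIM",
            "sample": f"SIM_R{int(rng.integers(1, 6))}",
            "chrom": chrom,
            "pos": pos,
            "ref": "C",
            "alt": "T",
            "depth": depth,
            "alt_reads": alt,
            "plus_strand_alt": plus,
            "minus_strand_alt": alt - plus,
            "gene": f"GENE{int(rng.integers(1, 2000)):04d}",
            "func": "exonic",
            "exonic_func": "nonsynonymous SNV",
            "dbsnp_af": 0.0,
            "converge_af": 0.0,
            "kg_af": 0.0,
            "esp_af": 0.0,
            "exac_af": 0.0,
            "sift": "tolerated",
            "polyphen": "benign",
            "context": "A[C>T]G",
            "kg_gold_indel": False,
        }
        if rng.random() < violation_fraction:
            crit = CRITERIA[int(rng.integers(len(CRITERIA)))]
            if crit == "strand_bias":
                rec["plus_strand_alt"], rec["minus_strand_alt"] = alt, 0
            elif crit == "depth":
                # keep alt >= 2 and strands balanced so no earlier criterion fires
                d = int(rng.integers(2, 20))
                rec["depth"], rec["alt_reads"] = d, min(alt, d)
                rec["plus_strand_alt"] = rec["alt_reads"] // 2
                rec["minus_strand_alt"] = rec["alt_reads"] - rec["plus_strand_alt"]
            elif crit == "alt_reads":
                a = int(rng.integers(2, 8))
                rec["alt_reads"] = a
                rec["plus_strand_alt"] = a // 2
                rec["minus_strand_alt"] = a - a // 2
            elif crit == "vaf":
                d = int(rng.integers(120, 300))
                a = int(rng.integers(8, max(9, int(0.1 * d))))
                rec["depth"], rec["alt_reads"] = d, a
                rec["plus_strand_alt"] = a // 2
                rec["minus_strand_alt"] = a - a // 2
            elif crit == "dbsnp_af":
                rec["dbsnp_af"] = float(rng.uniform(0.01, 0.5))
            elif crit == "converge":
                rec["converge_af"] = float(rng.uniform(0.01, 0.5))
            elif crit == "kg_gold_indel":
                rec["ref"], rec["alt"] = "C", "CA"
                rec["exonic_func"] = "frameshift insertion"
                rec["context"] = np.nan
                rec["kg_gold_indel"] = True
            elif crit == "pop_af_0.015":
                col = ["kg_af", "esp_af", "exac_af"][int(rng.integers(3))]
                rec[col] = float(rng.uniform(0.016, 0.5))
            elif crit == "region":
                rec["func"] = "intronic"
            truth.append(crit)
        else:
            truth.append("pass")
        rows.append(rec)
    df = pd.DataFrame(rows)
    return df, pd.Series(truth, name="expected")


# ---------------------------------------------------------------------------
# Cohort driver and writers


@dataclass
class Cohort:
    config: SimConfig
    patients: dict[str, tuple]  # pid -> (variants, expression, segments, truth)
    cytobands: pd.DataFrame

    @property
    def patient_ids(self) -> list[str]:
        return list(self.patients)

    def variants(self) -> pd.DataFrame:
        return pd.concat([v for v, _, _, _ in self.patients.values()], ignore_index=True)

    def segments(self) -> pd.DataFrame:
        return pd.concat([s for _, _, s, _ in self.patients.values()], ignore_index=True)

    def expression(self) -> ExpressionMatrix:
        mats = [e for _, e, _, _ in self.patients.values()]
        values = pd.concat([m.values for m in mats], axis=1)
        patient_of = {}
        for m in mats:
            patient_of.update(m.patient_of)
        return ExpressionMatrix(
            values=values,
            lengths=mats[0].lengths,
            value_kind=mats[0].value_kind,
            patient_of=patient_of,
        )

    def truths(self) -> dict[str, GroundTruth]:
        return {pid: t for pid, (_, _, _, t) in self.patients.items()}


def simulate_cohort(cfg: SimConfig) -> Cohort:
    """Simulate the full cohort under one configuration."""
    reference = mutsig.load_signature_matrix()
    bands = default_cytobands()
    patients = {}
    for i in range(cfg.n_patients):
        pid = f"P{i + 1:02d}"
        patients[pid] = simulate_patient(cfg, pid, reference=reference, cytobands=bands)
    return Cohort(config=cfg, patients=patients, cytobands=bands)


def write_cohort(cohort: Cohort, outdir) -> None:
    """Write the cohort as plain-text inputs for the file-based pipeline."""
    from .cnv_ith import write_seg
    from .expr_ith import write_counts_tsv

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_variants_tsv(cohort.variants(), out / "variants.tsv")
    write_seg(cohort.segments(), out / "segments.seg")
    write_counts_tsv(cohort.expression(), out / "counts.tsv")
    write_cytobands(cohort.cytobands, out / "cytobands.txt")
    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    for pid, truth in cohort.truths().items():
        (truth_dir / f"{pid}.json").write_text(truth.to_json() + "\n")
    patient_map = pd.DataFrame(
        [
            (s, pid)
            for pid, (_, expr, _, _) in cohort.patients.items()
            for s in expr.samples
        ],
        columns=["sample", "patient"],
    )
    patient_map.to_csv(out / "patients.tsv", sep="\t", index=False)
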