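"""End-to-end per-patient orchestration and consolidated reports.

``run_all`` drives the full per-patient pipeline - somatic filtering,
mutation matrix and parsimony tree, trunk/shared/private classes and
ITH scores, driver flagging, trunk-versus-non-trunk spectra and
signature exposures, cytoband CNV ubiquity, and expression clustering
with DEGs and the pooled HLA/CIITA association - from in-memory tables
or from the plain-text file formats the simulator writes.  Stages skip
gracefully when a data modality is absent; every report records the
seed and the ITH definitions explicitly.  Reports are plain JSON with
sorted keys, so identical inputs and seed reproduce byte-identical
bundles.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cnv_ith, drivers, expr_ith, mutsig, phylo_ith, simdata, variant_filter

log = logging.getLogger("ithpipe")


@dataclass
class RunConfig:
    """Inputs and per-stage parameters for one pipeline run."""

    variants_path: str | None = None
    variants_dialect: str = "tsv"
    seg_path: str | None = None
    cytobands_path: str | None = None
    counts_path: str | None = None
    lengths_path: str | None = None
    patients_path: str | None = None
    gmt_path: str | None = None
    driver_genes_path: str | None = None
    out_dir: str | None = None
    seed: int = 0
    filter: dict = field(default_factory=dict)
    phylo_iterations: int = 50
    ith_definition: str = "methods"
    cnv_t_amp: float = 0.3
    cnv_t_del: float = 0.3
    cnv_mode: str = "weighted"
    cnv_whitelist: list[str] | None = None
    expr_min_mean_log2: float = 1.0
    expr_min_mad_log2: float = 1.0
    deg_fc_high: float = 2.0
    deg_fc_low: float = 0.5

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        for name in (
            "variants_path", "seg_path", "cytobands_path", "counts_path",
            "lengths_path", "patients_path", "gmt_path", "driver_genes_path",
        ):
            p = getattr(cfg, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")
        return cfg


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        if np.isnan(obj):
            return None
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj), ndigits)
    return obj


def _patient_seed(seed: int, index: int) -> int:
    return (seed * 100_003 + 7 * index + 13) % (2**31)


def analyze_patient_variants(
    records: pd.DataFrame,
    patient_id: str,
    reference: pd.DataFrame,
    gene_list: drivers.DriverGeneList | None,
    iterations: int,
    seed: int,
) -> dict:
    """Phylogeny, classes, ITH, drivers and signatures for one patient."""
    matrix = phylo_ith.build_matrix(records, include_silent=True)
    result = phylo_ith.parsimony_ratchet(matrix, iterations=iterations, seed=seed)
    labels = dict(zip(result.mutation_ids, result.labels))
    counts = pd.Series(result.labels).value_counts()
    report: dict = {
        "patient": patient_id,
        "seed": seed,
        "mutations": {
            "total": int(matrix.n_mutations),
            "trunk": int(counts.get("trunk", 0)),
            "shared": int(counts.get("shared", 0)),
            "private": int(counts.get("private", 0)),
            "silent": int(matrix.silent.sum()),
        },
        "ith": dict(result.ith),
        "tree": result.newick,
        "parsimony_score": result.parsimony_score,
        "n_homoplastic": int(result.homoplastic.sum()),
    }
    if gene_list is not None:
        flagged = drivers.flag_drivers(records, gene_list)
        grid = drivers.driver_matrix(flagged, labels)
        report["drivers"] = {
            "n_mutations": int(flagged["driver"].sum()),
            "genes": sorted(grid.table["gene"].unique()),
            "truncal_genes": sorted(
                grid.table.loc[grid.table["truncal"], "gene"].unique()
            ),
        }
    mut_keys = [
        phylo_ith.mutation_key(c, p, r, a)
        for c, p, r, a in zip(records["chrom"], records["pos"], records["ref"], records["alt"])
    ]
    rec_labels = [
        "trunk" if labels.get(k) == "trunk" else "non-trunk" for k in mut_keys
    ]
    dedup = records.assign(_key=mut_keys, _lab=rec_labels).drop_duplicates("_key")
    spectra = mutsig.spectrum(dedup, labels=dedup["_lab"], subsets=("trunk", "non-trunk"))
    sig_report = {}
    for name, prof in spectra.items():
        entry = {"n_snvs": prof.total, "class6": prof.class6.tolist()}
        if prof.total >= 1:
            exp = mutsig.deconvolve(prof, reference)
            entry["exposures"] = exp.weights
            entry["residual"] = exp.residual
        sig_report[name] = entry
    if spectra["trunk"].total > 0 and spectra["non-trunk"].total > 0:
        test = mutsig.compare_spectra(spectra["trunk"], spectra["non-trunk"])
        sig_report["comparison"] = {"statistic": test.statistic, "df": test.df, "pvalue": test.pvalue}
    report["signatures"] = sig_report
    return report


def analyze_patient_cnv(
    segments: pd.DataFrame, bands: pd.DataFrame, cfg: RunConfig
) -> dict:
    filtered, n_removed = cnv_ith.filter_segments(segments)
    calls = cnv_ith.call_cytobands(
        filtered, bands, t_amp=cfg.cnv_t_amp, t_del=cfg.cnv_t_del,
        mode=cfg.cnv_mode, whitelist=cfg.cnv_whitelist,
    )
    ubiq = cnv_ith.ubiquity(calls.calls)
    nonneutral = calls.calls.apply(lambda row: set(row) != {"neutral"}, axis=1)
    return {
        "n_segments_removed_xy": n_removed,
        "ubiquitous": sorted(ubiq.index[(ubiq == "ubiquitous")]),
        "heterogeneous": sorted(ubiq.index[(ubiq == "heterogeneous") & nonneutral]),
        "n_absent": int((ubiq == "absent").sum()),
    }


def analyze_patient_expression(
    expr: expr_ith.ExpressionMatrix,
    samples: list[str],
    cfg: RunConfig,
    gene_sets: dict | None,
) -> dict:
    rp = expr_ith.rpkm(expr)
    sub = rp.values[samples]
    variable = expr_ith.select_variable_genes(
        sub, min_mean_log2=cfg.expr_min_mean_log2, min_mad_log2=cfg.expr_min_mad_log2
    )
    out: dict = {"n_samples": len(samples), "n_variable_genes": int(len(variable))}
    if len(variable) < 1 or len(samples) < 2:
        out["status"] = "too few variable genes"
        return out
    groups, _ = expr_ith.cluster_two_groups(variable)
    degs = expr_ith.identify_degs(
        sub, groups, fc_high=cfg.deg_fc_high, fc_low=cfg.deg_fc_low
    )
    out["groups"] = {s: int(g) for s, g in groups.items()}
    out["n_degs"] = degs.n
    if gene_sets:
        enr = expr_ith.enrich(degs.genes, list(sub.index), gene_sets)
        out["enrichment_top"] = enr.head(5)[["set", "overlap", "pvalue", "padj"]].to_dict("records")
    return out


def run_all(cfg: RunConfig) -> dict:
    """Run every stage for which inputs are present; return the report bundle.

    The bundle maps patient id to per-patient report plus a ``cohort``
    entry (medians, pooled HLA association).  With ``cfg.out_dir`` set,
    one JSON per patient plus ``cohort.json`` are written.
    """
    t0 = time.time()
    if cfg.variants_path is None and cfg.counts_path is None and cfg.seg_path is None:
        raise ValueError("at least one data modality (variants, CNV, expression) required")
    reference = mutsig.load_signature_matrix()
    gene_list = (
        drivers.DriverGeneList.from_file(cfg.driver_genes_path)
        if cfg.driver_genes_path
        else drivers.DriverGeneList.example()
    )
    gene_sets = expr_ith.read_gmt(cfg.gmt_path) if cfg.gmt_path else None

    variants = None
    if cfg.variants_path:
        variants = variant_filter.read_variants(cfg.variants_path, dialect=cfg.variants_dialect)
    segments = cnv_ith.read_seg(cfg.seg_path) if cfg.seg_path else None
    bands = (
        cnv_ith.read_cytobands(cfg.cytobands_path)
        if cfg.cytobands_path
        else simdata.default_cytobands()[["cytoband", "chrom", "start", "end"]]
    )
    expr = None
    patient_of: dict[str, str] = {}
    if cfg.counts_path:
        expr = expr_ith.read_counts_tsv(cfg.counts_path, lengths_path=cfg.lengths_path)
        if cfg.patients_path:
            pm = pd.read_csv(cfg.patients_path, sep="\t")
            patient_of = dict(zip(pm["sample"].astype(str), pm["patient"].astype(str)))
        else:
            patient_of = {s: s.rsplit("_", 1)[0] for s in expr.samples}
        expr.patient_of = patient_of

    patient_ids: set[str] = set()
    if variants is not None:
        patient_ids |= set(variants["patient"].astype(str))
    if expr is not None:
        patient_ids |= set(patient_of.values())
    if segments is not None and variants is not None:
        var_samples = set(variants["sample"].astype(str))
        seg_samples = set(segments["sample_id"].astype(str))
        if not (var_samples & seg_samples):
            raise ValueError(
                "sample ids in the CNV segments share nothing with the variant "
                "table; cross-modality ids must agree"
            )
    if variants is not None and expr is not None:
        if not (set(variants["patient"].astype(str)) & set(patient_of.values())):
            raise ValueError("patient ids disagree between variants and expression")

    bundle: dict = {}
    filter_report = None
    passing = None
    if variants is not None:
        fc = variant_filter.FilterConfig(**cfg.filter)
        passing, filter_report = variant_filter.apply_somatic_filters(variants, fc)
        log.info("filter: %d/%d records pass", filter_report.n_pass, filter_report.n_input)

    for idx, pid in enumerate(sorted(patient_ids)):
        report: dict = {"patient": pid}
        pseed = _patient_seed(cfg.seed, idx)
        if passing is not None:
            pv = passing[passing["patient"].astype(str) == pid]
            if len(pv) and pv["sample"].nunique() >= 2:
                report.update(
                    analyze_patient_variants(
                        pv, pid, reference, gene_list, cfg.phylo_iterations, pseed
                    )
                )
            else:
                report["mutations"] = "absent"
        else:
            report["mutations"] = "absent"
        if segments is not None:
            samp = {s for s in segments["sample_id"].astype(str) if s.rsplit("_", 1)[0] == pid}
            seg_p = segments[segments["sample_id"].astype(str).isin(samp)]
            report["cnv"] = (
                analyze_patient_cnv(seg_p, bands, cfg) if len(seg_p) else "absent"
            )
        else:
            report["cnv"] = "absent"
        if expr is not None:
            samples = [s for s in expr.samples if patient_of.get(s) == pid]
            report["expression"] = (
                analyze_patient_expression(expr, samples, cfg, gene_sets)
                if len(samples) >= 2
                else "absent"
            )
        else:
            report["expression"] = "absent"
        bundle[pid] = report

    cohort: dict = {"seed": cfg.seed, "n_patients": len(patient_ids)}
    if filter_report is not None:
        cohort["filter"] = json.loads(filter_report.to_json())
    ith_m = [
        b["ith"]["methods"] for b in bundle.values()
        if isinstance(b.get("ith"), dict) and b["ith"]["methods"] is not None
        and not np.isnan(b["ith"]["methods"])
    ]
    ith_nf = [
        b["ith"]["nontrunk_fraction"] for b in bundle.values() if isinstance(b.get("ith"), dict)
    ]
    if ith_m:
        cohort["ith_methods"] = {
            "median": float(np.median(ith_m)),
            "range": [float(np.min(ith_m)), float(np.max(ith_m))],
        }
    if ith_nf:
        cohort["ith_nontrunk_fraction"] = {
            "median": float(np.median(ith_nf)),
            "range": [float(np.min(ith_nf)), float(np.max(ith_nf))],
        }
    cohort["ith_definition_default"] = cfg.ith_definition
    if expr is not None:
        rp = expr_ith.rpkm(expr)
        panel = expr_ith.HlaPanel()
        if panel.regulator in rp.values.index:
            assoc = expr_ith.hla_association(rp.values, panel)
            cohort["hla_association"] = assoc.to_dict("records")
    deg_counts = [
        b["expression"]["n_degs"]
        for b in bundle.values()
        if isinstance(b.get("expression"), dict) and "n_degs" in b["expression"]
    ]
    if deg_counts:
        cohort["degs"] = {
            "median": float(np.median(deg_counts)),
            "range": [int(np.min(deg_counts)), int(np.max(deg_counts))],
        }
    cohort["runtime_s"] = round(time.time() - t0, 3)
    bundle["cohort"] = cohort

    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for pid, rep in bundle.items():
            name = "cohort.json" if pid == "cohort" else f"{pid}.json"
            payload = _round_floats(rep)
            if pid == "cohort":
                payload.pop("runtime_s", None)  # keep report bundles reproducible
            (out / name).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return bundle
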