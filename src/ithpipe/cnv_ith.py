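"""Cytoband-level copy-number calls and their within-patient ubiquity.

Per-sample log2-ratio segments (SEG dialect, produced upstream by a
tumor-versus-panel-of-normals caller) are summarised per cytoband as
the segment-length-weighted mean log2 ratio over the band; a band is
called *gain* when the summary exceeds +0.3 and *loss* below -0.3 (the
published amplification/deletion thresholds).  Chromosomes X and Y are
excluded before calling.  Within one patient a band is *ubiquitous*
when every region-sample carries the same non-neutral call,
*heterogeneous* when some but not all do (or calls conflict), and
*absent* when all samples are neutral.

Peak-significance machinery (G-scores, q-values) is out of scope; an
optional band whitelist emulates restricting the heat map to selected
peak cytobands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SEG_COLUMNS = ["sample_id", "chrom", "start", "end", "log2"]

SEX_CHROMS = {"X", "Y"}


def _norm_chrom(c) -> str:
    c = str(c)
    return c[3:] if c.lower().startswith("chr") else c


def read_seg(path) -> pd.DataFrame:
    """Read a SEG table (ID, chrom, loc.start, loc.end[, num.mark], seg.mean)."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}

    def pick(*names):
        for n in names:
            if n in cols:
                return cols[n]
        raise ValueError(f"SEG file {path}: none of {names} found in columns {list(df.columns)}")

    out = pd.DataFrame(
        {
            "sample_id": df[pick("id", "sample", "sample_id")].astype(str),
            "chrom": df[pick("chrom", "chromosome")].map(_norm_chrom),
            "start": df[pick("loc.start", "start")].astype(int),
            "end": df[pick("loc.end", "end")].astype(int),
            "log2": df[pick("seg.mean", "log2", "seg_mean")].astype(float),
        }
    )
    bad = out["start"] > out["end"]
    if bad.any():
        raise ValueError(f"SEG file {path}: {int(bad.sum())} segment(s) with start > end")
    return out


def write_seg(segments: pd.DataFrame, path) -> None:
    out = segments.rename(
        columns={"sample_id": "ID", "chrom": "chrom", "start": "loc.start", "end": "loc.end", "log2": "seg.mean"}
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_cytobands(path) -> pd.DataFrame:
    """Read a UCSC-style cytoBand file (BED-like, 0-based half-open).

    Returns 1-based inclusive intervals with ids like ``9p21.3``.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start0", "end", "band", "stain"],
        usecols=[0, 1, 2, 3, 4],
    )
    chrom = df["chrom"].map(_norm_chrom)
    return pd.DataFrame(
        {
            "cytoband": chrom + df["band"].astype(str),
            "chrom": chrom,
            "start": df["start0"].astype(int) + 1,
            "end": df["end"].astype(int),
        }
    )


def filter_segments(segments: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop X/Y segments; returns (autosomal segments, number removed)."""
    chrom = segments["chrom"].map(_norm_chrom).str.upper()
    keep = ~chrom.isin(SEX_CHROMS)
    out = segments[keep].copy()
    out["chrom"] = chrom[keep]
    return out.reset_index(drop=True), int((~keep).sum())


@dataclass
class CytobandCallMatrix:
    """Bands x samples call grid plus per-band no-coverage flags."""

    calls: pd.DataFrame  # index cytoband, columns samples, values gain/loss/neutral
    values: pd.DataFrame  # the summarised log2 values (NaN where uncovered)

    @property
    def cytobands(self) -> list[str]:
        return list(self.calls.index)

    @property
    def samples(self) -> list[str]:
        return list(self.calls.columns)


def call_cytobands(
    segments: pd.DataFrame,
    cytobands: pd.DataFrame,
    t_amp: float = 0.3,
    t_del: float = 0.3,
    mode: str = "weighted",
    whitelist: list[str] | None = None,
) -> CytobandCallMatrix:
    """Summarise segments per cytoband per sample and call gain/loss.

    ``mode="weighted"`` uses the overlap-length-weighted mean log2
    ratio; ``mode="extreme"`` the overlapping value of largest
    magnitude.  Gain iff summary > `t_amp`; loss iff summary < -`t_del`
    (strict inequalities).  Bands with no overlapping segment are
    neutral with a missing value.  Segments on chromosomes absent from
    the cytoband table are skipped with a warning.
    """
    import warnings

    if mode not in ("weighted", "extreme"):
        raise ValueError(f"unknown summarisation mode {mode!r}")
    segs = segments.copy()
    segs["chrom"] = segs["chrom"].map(_norm_chrom)
    bands = cytobands.copy()
    bands["chrom"] = bands["chrom"].map(_norm_chrom)
    if whitelist is not None:
        bands = bands[bands["cytoband"].isin(set(whitelist))]
    unknown = set(segs["chrom"]) - set(bands["chrom"])
    if unknown:
        warnings.warn(f"segments on chromosome(s) {sorted(unknown)} have no cytobands; skipped")
        segs = segs[~segs["chrom"].isin(unknown)]
    samples = sorted(segs["sample_id"].unique())
    band_ids = list(bands["cytoband"])
    values = pd.DataFrame(np.nan, index=band_ids, columns=samples)
    for chrom, bgrp in bands.groupby("chrom", sort=False):
        schrom = segs[segs["chrom"] == chrom]
        if schrom.empty:
            continue
        for sample, sgrp in schrom.groupby("sample_id"):
            s_start = sgrp["start"].to_numpy()
            s_end = sgrp["end"].to_numpy()
            s_val = sgrp["log2"].to_numpy()
            for _, band in bgrp.iterrows():
                ov = np.minimum(s_end, band["end"]) - np.maximum(s_start, band["start"]) + 1
                hit = ov > 0
                if not hit.any():
                    continue
                if mode == "weighted":
                    w = ov[hit].astype(float)
                    values.loc[band["cytoband"], sample] = float(
                        (s_val[hit] * w).sum() / w.sum()
                    )
                else:
                    values.loc[band["cytoband"], sample] = float(
                        s_val[hit][np.argmax(np.abs(s_val[hit]))]
                    )
    calls = pd.DataFrame("neutral", index=band_ids, columns=samples, dtype=object)
    calls = calls.mask(values > t_amp, "gain").mask(values < -t_del, "loss")
    calls[values.isna()] = "neutral"
    return CytobandCallMatrix(calls=calls, values=values)


def ubiquity(calls: pd.DataFrame) -> pd.Series:
    """Per-cytoband ubiquity labels for one patient's call matrix.

    Requires >=2 samples.  Uncovered (missing) cells count as neutral.
    """
    if calls.shape[1] < 2:
        raise ValueError("ubiquity classification needs >=2 samples")
    out = {}
    for band, row in calls.iterrows():
        vals = set(row)
        if vals == {"neutral"}:
            out[band] = "absent"
        elif len(vals) == 1:
            out[band] = "ubiquitous"
        else:
            out[band] = "heterogeneous"
    return pd.Series(out, name="ubiquity")
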