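"""Mutational spectra and signature deconvolution.

Single-base substitutions are summarised in two resolutions: the six
pyrimidine-centred change classes (C>A, C>G, C>T, T>A, T>C, T>G) and
the 96 trinucleotide-context categories obtained by crossing each
change class with its 5' and 3' flanking bases.  Substitutions reported
on the purine strand are reverse-complemented into the pyrimidine
frame, so each of the 192 raw (substitution, context) combinations maps
onto exactly one of 96 categories.

A tumor spectrum is modelled as a non-negative mixture of reference
signature profiles (probability distributions over the 96 categories).
Exposures are estimated by greedy forward selection with non-negative
least squares, mirroring the deconstructSigs procedure: signatures are
added one at a time while the squared reconstruction error keeps
improving, small exposures are discarded, and the remainder is
renormalised.

The bundled reference matrix (30 signatures x 96 contexts) is a
synthetic stand-in generated by ``scripts/make_signature_reference.py``;
see :func:`load_signature_matrix`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

SUBSTITUTIONS: tuple[str, ...] = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = "ACGT"

#: The 96 trinucleotide categories in fixed order: substitution-major,
#: then 5' flank, then 3' flank, each alphabetical.
CONTEXT_96: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}" for sub in SUBSTITUTIONS for five in BASES for three in BASES
)
_CONTEXT_INDEX = {c: i for i, c in enumerate(CONTEXT_96)}
_CLASS_INDEX = {s: i for i, s in enumerate(SUBSTITUTIONS)}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

_REFERENCE_RESOURCE = "signatures_synthetic_30x96.tsv"


def classify_context(ref: str, alt: str, upstream: str, downstream: str) -> str:
    """Map a single-base substitution with its flanks to a 96-category label.

    Purine-reference substitutions are reverse-complemented into the
    pyrimidine frame, e.g. ``G>A`` flanked by T and C becomes
    ``G[C>T]A``.

    Parameters
    ----------
    ref, alt : str
        Reference and alternative base (single characters).
    upstream, downstream : str
        The base 5' and 3' of the substituted position, on the same
        strand as `ref`.
    """
    ref, alt = ref.upper(), alt.upper()
    upstream, downstream = upstream.upper(), downstream.upper()
    for b in (ref, alt, upstream, downstream):
        if b not in _COMPLEMENT:
            raise ValueError(f"non-ACGT base in substitution context: {b!r}")
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise ValueError(f"not a single-base substitution: {ref}>{alt}")
    if ref in "AG":  # purine frame -> reverse complement
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        upstream, downstream = _COMPLEMENT[downstream], _COMPLEMENT[upstream]
    return f"{upstream}[{ref}>{alt}]{downstream}"


def context_to_class(context: str) -> str:
    """Extract the six-class substitution (e.g. ``C>T``) from a 96-label."""
    sub = context[2:5]
    if context not in _CONTEXT_INDEX:
        raise ValueError(f"not a 96-category context label: {context!r}")
    return sub


@dataclass
class SpectrumProfile:
    """Mutation counts for one subset (trunk, non-trunk or all) of SNVs.

    ``class6`` and ``context96`` are integer count vectors in the fixed
    orders of :data:`SUBSTITUTIONS` and :data:`CONTEXT_96`; both sum to
    ``total``.  ``n_excluded`` counts non-SNV records (e.g. INDELs)
    dropped while building the profile.
    """

    label: str
    context96: np.ndarray
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.context96 = np.asarray(self.context96, dtype=np.int64)
        if self.context96.shape != (96,):
            raise ValueError("context96 must have length 96")
        if (self.context96 < 0).any():
            raise ValueError("negative counts")

    @property
    def class6(self) -> np.ndarray:
        return self.context96.reshape(6, 16).sum(axis=1)

    @property
    def total(self) -> int:
        return int(self.context96.sum())

    @property
    def fractions(self) -> np.ndarray:
        t = self.total
        return self.context96 / t if t else np.zeros(96)

    @classmethod
    def from_contexts(cls, contexts, label: str = "all", n_excluded: int = 0) -> "SpectrumProfile":
        counts = np.zeros(96, dtype=np.int64)
        for c in contexts:
            counts[_CONTEXT_INDEX[c]] += 1
        return cls(label=label, context96=counts, n_excluded=n_excluded)

    def to_series(self) -> pd.Series:
        return pd.Series(self.context96, index=list(CONTEXT_96), name=self.label)


def _context_of_record(row: pd.Series, context_col: str, fasta) -> str | None:
    """Resolve the 96-label for one SNV row; None if unavailable."""
    val = row.get(context_col)
    if isinstance(val, str) and val:
        if "[" in val:
            if val not in _CONTEXT_INDEX:
                raise ValueError(f"bad context label {val!r} at {row['chrom']}:{row['pos']}")
            return val
        if len(val) == 3:
            return classify_context(row["ref"], row["alt"], val[0], val[2])
    if fasta is not None:
        chrom, pos = row["chrom"], int(row["pos"])
        trip = str(fasta[chrom][pos - 2 : pos + 1]).upper()
        return classify_context(row["ref"], row["alt"], trip[0], trip[2])
    return None


def spectrum(
    records: pd.DataFrame,
    labels=None,
    subsets: tuple[str, ...] | None = None,
    context_col: str = "context",
    fasta=None,
) -> dict[str, SpectrumProfile]:
    """Build spectra for SNV records, optionally split by subset label.

    Parameters
    ----------
    records : DataFrame
        Variant table with ``chrom, pos, ref, alt`` and either a context
        column (96-label such as ``A[C>T]G`` or a raw triplet) or a
        `pyfaidx.Fasta` for sequence lookup.
    labels : sequence of str, optional
        Per-record subset labels (e.g. trunk / non-trunk); when omitted
        a single profile labelled ``all`` is returned.
    subsets : tuple, optional
        Restrict / order the returned profiles.

    Returns
    -------
    dict mapping subset label to :class:`SpectrumProfile`.  Non-SNV
    records are excluded and counted in ``n_excluded``.
    """
    if labels is None:
        labels = pd.Series("all", index=records.index)
    else:
        labels = pd.Series(list(labels), index=records.index)
    is_snv = (
        records["ref"].str.len().eq(1)
        & records["alt"].str.len().eq(1)
        & records["ref"].str.upper().isin(list(BASES))
        & records["alt"].str.upper().isin(list(BASES))
    )
    out: dict[str, SpectrumProfile] = {}
    wanted = subsets if subsets is not None else tuple(dict.fromkeys(labels))
    for sub in wanted:
        members = records[labels == sub]
        snvs = members[is_snv.reindex(members.index, fill_value=False)]
        contexts = []
        for _, row in snvs.iterrows():
            ctx = _context_of_record(row, context_col, fasta)
            if ctx is None:
                raise ValueError(
                    f"no trinucleotide context for {row['chrom']}:{row['pos']} "
                    f"{row['ref']}>{row['alt']} and no FASTA supplied"
                )
            contexts.append(ctx)
        out[sub] = SpectrumProfile.from_contexts(
            contexts, label=str(sub), n_excluded=len(members) - len(snvs)
        )
    return out


@dataclass
class SpectrumTest:
    statistic: float
    df: int
    pvalue: float
    mode: str
    per_class: dict[str, float] = field(default_factory=dict)


def compare_spectra(a: SpectrumProfile, b: SpectrumProfile, mode: str = "global") -> SpectrumTest:
    """Proportions test between two six-class spectra.

    ``mode="global"`` performs the chi-square test of homogeneity on
    the 2x6 class table (continuity correction applies automatically
    when the non-empty table collapses to 2x2, per standard practice).
    ``mode="per_class"`` performs six Yates-corrected 2x2 tests of each
    class against the rest, mirroring per-class significance stars.
    """
    if a.total == 0 or b.total == 0:
        raise ValueError("cannot compare a zero-total spectrum")
    table = np.vstack([a.class6, b.class6])
    if mode == "global":
        keep = table.sum(axis=0) > 0
        t = table[:, keep]
        if t.shape[1] < 2:
            return SpectrumTest(0.0, 0, 1.0, mode)
        stat, p, dof, _ = stats.chi2_contingency(t, correction=(t.shape[1] == 2))
        return SpectrumTest(float(stat), int(dof), float(p), mode)
    if mode == "per_class":
        per = {}
        for i, cls in enumerate(SUBSTITUTIONS):
            t = np.array(
                [
                    [table[0, i], a.total - table[0, i]],
                    [table[1, i], b.total - table[1, i]],
                ]
            )
            if t[:, 0].sum() == 0 or t[:, 1].sum() == 0:
                per[cls] = 1.0
                continue
            _, p, _, _ = stats.chi2_contingency(t, correction=True)
            per[cls] = float(p)
        pmin = min(per.values())
        return SpectrumTest(float("nan"), 1, pmin, mode, per_class=per)
    raise ValueError(f"unknown mode {mode!r}")


def load_signature_matrix(path=None) -> pd.DataFrame:
    """Load a reference signature matrix (96 contexts x K signatures).

    Without `path`, returns the bundled synthetic 30-signature matrix
    (a generated stand-in with the field's qualitative structure:
    Signature 1 is C>T-at-NpCpG dominated, Signature 4 is C>A
    dominated, Signature 17 is T>G dominated, and so on), suitable for
    simulation and recovery experiments.  Rows are reindexed to the
    fixed :data:`CONTEXT_96` order; columns are validated to sum to 1.
    """
    if path is None:
        ref = resources.files("ithpipe.data").joinpath(_REFERENCE_RESOURCE)
        with resources.as_file(ref) as p:
            mat = pd.read_csv(p, sep="\t", index_col=0)
    else:
        mat = pd.read_csv(path, sep="\t", index_col=0)
    missing = set(CONTEXT_96) - set(mat.index)
    if missing:
        raise ValueError(f"signature matrix missing contexts: {sorted(missing)[:3]}...")
    mat = mat.loc[list(CONTEXT_96)]
    sums = mat.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("signature columns must each sum to 1")
    return mat


def mixture_distribution(mix: dict[str, float], reference: pd.DataFrame) -> np.ndarray:
    """The 96-category distribution of a signature mixture."""
    missing = set(mix) - set(reference.columns)
    if missing:
        raise ValueError(f"mixture names not in reference: {sorted(missing)}")
    w = np.array([mix.get(c, 0.0) for c in reference.columns])
    if abs(w.sum() - 1.0) > 1e-9 or (w < 0).any():
        raise ValueError("mixture weights must be non-negative and sum to 1")
    dist = reference.to_numpy() @ w
    return dist / dist.sum()  # absorb file-precision rounding


@dataclass
class ExposureResult:
    """Signature exposures for one spectrum.

    ``weights`` are the kept exposures renormalised to sum to 1 (empty
    when everything fell below the discard threshold); ``residual`` is
    the fraction of the spectrum left unexplained before
    renormalisation; ``reconstruction_error`` is the squared L2 error
    of the final weighted reconstruction against the observed
    fractions.
    """

    weights: dict[str, float]
    residual: float
    reconstruction_error: float
    selection_order: list[str] = field(default_factory=list)


def deconvolve(
    profile: SpectrumProfile,
    reference: pd.DataFrame,
    discard_threshold: float = 0.06,
    min_improvement: float = 1e-3,
    context_weights: np.ndarray | None = None,
) -> ExposureResult:
    """Greedy non-negative signature deconvolution of a 96-spectrum.

    Forward selection: at each step the signature whose inclusion (with
    all selected weights refit by non-negative least squares) most
    reduces the squared reconstruction error is added; the loop stops
    when the relative improvement falls below `min_improvement`.
    Exposure fractions not exceeding `discard_threshold` are then zeroed
    and the rest renormalised.

    `context_weights`, when given, rescales the observed fractions by
    per-context abundance weights (e.g. exome vs genome trinucleotide
    frequencies) before fitting; default is no rescaling.
    """
    if profile.total < 1:
        raise ValueError("cannot deconvolve an empty spectrum")
    S = reference.to_numpy(dtype=float)
    if S.shape[0] != 96:
        raise ValueError("reference must have 96 context rows")
    p = profile.fractions.astype(float)
    if context_weights is not None:
        context_weights = np.asarray(context_weights, dtype=float)
        if context_weights.shape != (96,) or (context_weights <= 0).any():
            raise ValueError("context_weights must be 96 positive values")
        p = p * context_weights
        p = p / p.sum()
    names = list(reference.columns)
    selected: list[int] = []
    err = float(p @ p)
    weights_sel = np.zeros(0)
    while len(selected) < len(names):
        best = None
        for j in range(len(names)):
            if j in selected:
                continue
            cols = selected + [j]
            w, rnorm = nnls(S[:, cols], p)
            e = rnorm**2
            if best is None or e < best[0]:
                best = (e, j, w)
        new_err, j, w = best
        if err > 0 and (err - new_err) / err < min_improvement:
            break
        selected.append(j)
        weights_sel = w
        err = new_err
        if err <= 1e-12:
            break
    raw = np.zeros(len(names))
    for idx, j in enumerate(selected):
        raw[j] = weights_sel[idx]
    total_w = raw.sum()
    frac = raw / total_w if total_w > 0 else raw
    keep = frac > discard_threshold
    kept_frac = frac[keep]
    residual = float(1.0 - kept_frac.sum())
    if keep.any():
        final = np.zeros(len(names))
        final[keep] = kept_frac / kept_frac.sum()
        recon = S @ final
        rec_err = float(((p - recon) ** 2).sum())
        weights = {names[j]: float(final[j]) for j in np.flatnonzero(keep)}
    else:
        residual = 1.0
        rec_err = float(p @ p)
        weights = {}
    return ExposureResult(
        weights=weights,
        residual=residual,
        reconstruction_error=rec_err,
        selection_order=[names[j] for j in selected],
    )


def exposures_to_frame(exposures: dict[str, ExposureResult]) -> pd.DataFrame:
    """Tabulate exposures (rows: signatures, columns: subsets)."""
    cols = {}
    for label, res in exposures.items():
        cols[label] = pd.Series(res.weights, dtype=float)
    frame = pd.DataFrame(cols).fillna(0.0)
    return frame.sort_index()


def warn_if_sparse(profile: SpectrumProfile, min_total: int = 50) -> None:
    if profile.total < min_total:
        warnings.warn(
            f"spectrum {profile.label!r} has only {profile.total} SNVs; "
            "exposure estimates will be unstable",
            stacklevel=2,
        )
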