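"""Regenerate the bundled synthetic 30-signature reference matrix.

The shipped file ``src/ithpipe/data/signatures_synthetic_30x96.tsv`` is
a deterministic synthetic stand-in for a 30-signature trinucleotide
reference: each column is a probability distribution over the 96
pyrimidine-centred contexts.  A handful of named signatures reproduce
the qualitative character relied on downstream (Signature 1: C>T at
NpCpG; Signature 2: C>T/C>G at TpCpN; Signature 4: broad C>A;
Signatures 6/15: C>T-rich with distinct context preferences;
Signature 7: C>T at YpCpN; Signature 17: T>G at NpTpT).  The remaining
columns are sparse random profiles, which keeps the dictionary
well-conditioned for mixture-recovery experiments.

Run from the repository root:

    python scripts/make_signature_reference.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

BASES = "ACGT"
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
CONTEXTS = [f"{f}[{s}]{t}" for s in SUBSTITUTIONS for f in BASES for t in BASES]
IDX = {c: i for i, c in enumerate(CONTEXTS)}


def _mask(sub=None, five=None, three=None):
    sel = np.zeros(96, dtype=bool)
    for c in CONTEXTS:
        s, f, t = c[2:5], c[0], c[6]
        if sub is not None and s not in sub:
            continue
        if five is not None and f not in five:
            continue
        if three is not None and t not in three:
            continue
        sel[IDX[c]] = True
    return sel


def build(seed: int = 20210404) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    K = 30
    cols = np.zeros((96, K))
    structured = {
        # name (1-based) -> list of (mask, mass)
        1: [(_mask(sub=("C>T",), three="G"), 0.75)],
        2: [(_mask(sub=("C>T",), five="T"), 0.45), (_mask(sub=("C>G",), five="T"), 0.30)],
        4: [(_mask(sub=("C>A",)), 0.75)],
        5: [(_mask(sub=("T>C",)), 0.55)],
        6: [(_mask(sub=("C>T",), five="G", three="AC"), 0.65)],
        7: [(_mask(sub=("C>T",), five="CT", three="CT"), 0.70)],
        13: [(_mask(sub=("C>G",), five="T"), 0.70)],
        15: [(_mask(sub=("C>T",), five="AC", three="T"), 0.65)],
        17: [(_mask(sub=("T>G",), three="T"), 0.75)],
    }
    for k in range(K):
        name_no = k + 1
        # sparse random background: mass on a random dozen contexts
        bg = np.full(96, 1e-4)
        peaks = rng.choice(96, size=12, replace=False)
        bg[peaks] += rng.dirichlet(np.full(12, 0.4))
        bg /= bg.sum()
        if name_no in structured:
            col = np.zeros(96)
            used = 0.0
            for mask, mass in structured[name_no]:
                sub = np.zeros(96)
                sub[mask] = rng.dirichlet(np.full(mask.sum(), 1.5))
                col += mass * sub
                used += mass
            col += (1.0 - used) * bg
        else:
            col = bg
        cols[:, k] = col / col.sum()
    frame = pd.DataFrame(
        cols, index=CONTEXTS, columns=[f"Signature {i}" for i in range(1, K + 1)]
    )
    return frame


def main() -> None:
    out = Path(__file__).resolve().parents[1] / "src" / "ithpipe" / "data"
    out.mkdir(parents=True, exist_ok=True)
    frame = build()
    dest = out / "signatures_synthetic_30x96.tsv"
    frame.to_csv(dest, sep="\t", float_format="%.6e")
    print(f"wrote {dest} ({dest.stat().st_size} bytes)")


if __name__ == "__main__":
    main()
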