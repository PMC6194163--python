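"""Synthetic mitochondrial reference sequence and coordinate conventions.

The human mitochondrial genome is a 16,569 bp circle numbered 1..16569 in the
revised Cambridge Reference Sequence (rCRS) coordinate system; the historical
placeholder at position 3107 is omitted, so coordinates here are contiguous.

The sequence shipped by this module is *synthetic*: a deterministic
pseudo-random 16,569 nt sequence generated from a fixed internal seed, with
the reference alleles at the classical pathogenic sites pinned to their rCRS
values (m.3243 A, m.11778 G, m.13513 G, m.14484 T).  All coordinate
arithmetic, heteroplasmy calling and breakpoint placement are content-
agnostic, so a synthetic sequence supports the full pipeline without shipping
genomic data.
"""

from __future__ import annotations

import importlib.resources

import numpy as np

MT_LENGTH = 16569

#: D-loop / control region excluded from pathogenic-variant calling.
#: Standard control-region bounds; the wrap-around region is represented as
#: two closed 1-based intervals.
DLOOP_INTERVALS = ((16024, 16569), (1, 576))

#: rCRS reference alleles at classical pathogenic sites (pinned into the
#: synthetic sequence so known-variant lookups behave as on the real genome).
PINNED_ALLELES = {3243: "A", 11778: "G", 13513: "G", 14484: "T"}

_REFERENCE_SEED = 316569  # fixed: the reference is a coordinate system, not a sample

#: Deletion junctions planted by the cohort simulator.  The synthetic
#: sequence is adjusted so no direct repeat spans these junction boundaries:
#: each planted (b5, b3) is then its own leftmost representation and callers
#: report exactly these coordinates.  (On the real genome several recurrent
#: deletions are repeat-flanked and printed coordinates are a convention.)
PINNED_JUNCTIONS = (
    (8482, 13460),
    (7462, 15747),
    (9514, 15792),
    (6330, 13993),
    (7974, 15496),
)


def in_dloop(position: int) -> bool:
    """True if a 1-based position falls in the control region."""
    return any(lo <= position <= hi for lo, hi in DLOOP_INTERVALS)


def mt_reference() -> str:
    """Return the synthetic 16,569 nt mitochondrial reference (cached)."""
    global _REF
    if _REF is None:
        rng = np.random.default_rng(_REFERENCE_SEED)
        bases = np.array(list("ACGT"))
        seq = bases[rng.integers(0, 4, MT_LENGTH)]
        for pos, allele in PINNED_ALLELES.items():
            seq[pos - 1] = allele
        for b5, b3 in PINNED_JUNCTIONS:
            # forbid a left shift of the junction: last retained 5' base must
            # differ from the base preceding the 3' breakpoint
            while seq[b5 - 1] == seq[b3 - 2]:
                seq[b3 - 2] = "ACGT"[("ACGT".index(seq[b3 - 2]) + 1) % 4]
        _REF = "".join(seq)
    return _REF


_REF: str | None = None


def load_known_pathogenic() -> dict[tuple[int, str, str], dict]:
    """Load the packaged known-pathogenic mtDNA point-mutation table.

    Returns a map (position, ref, alt) -> {"label": syndrome label}.
    The table covers the classical alleles this pipeline must recognise
    (m.3243A>G, m.11778G>A, m.13513G>A, m.14484T>C).
    """
    table: dict[tuple[int, str, str], dict] = {}
    text = (
        importlib.resources.files("mitotriage.data")
        .joinpath("known_pathogenic_mtdna.tsv")
        .read_text()
    )
    for line in text.splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("position\t"):
            continue
        pos, ref, alt, label = line.rstrip("\n").split("\t")
        table[(int(pos), ref, alt)] = {"label": label}
    return table
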