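"""mtDNA-stage calling: heteroplasmic point variants, large-deletion
breakpoints from junction-spanning reads, copy-number depletion, and the
stage outcome.

Heteroplasmy is estimated as the mutant read depth over the total depth at
a site.  Calling uses a 2% cutoff for known pathogenic point mutations and
a 5% cutoff elsewhere (small indels included), both inclusive, and excludes
the hypervariable control region (D-loop).

Large deletions are placed by split-aligning junction-spanning reads
against the reference: the maximal reference match of the read's prefix and
of its suffix meet at the junction.  When the junction is flanked by a
direct repeat, every split point inside the repeat is sequence-equivalent;
the caller reports the leftmost representation and merges repeat-shifted
duplicates into one event.  The mitochondrial circle is handled by doubling
the linear reference and reducing coordinates modulo its length.

A single large deletion is a diagnosis; multiple distinct deletions or
copy-number depletion point to a nuclear mtDNA-maintenance defect and
escalate the family to exome analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .refseq import MT_LENGTH, in_dloop

KNOWN_CUTOFF = 0.02
NOVEL_CUTOFF = 0.05
DEFAULT_MIN_SUPPORT = 3
DEFAULT_DEPLETION_THRESHOLD = 35.0  # percent of control mean
MIN_ANCHOR = 20  # nt of exact reference match required on each side of a junction


@dataclass(frozen=True)
class MtPileup:
    """Per-position allele depths at a 1-based rCRS coordinate."""

    position: int
    ref: str
    depths: dict[str, int] = field(default_factory=dict)  # allele -> read depth

    @property
    def total_depth(self) -> int:
        return sum(self.depths.values())


@dataclass(frozen=True)
class MtRead:
    """A read with rCRS provenance; junction reads carry no alignment."""

    name: str
    sequence: str
    aligned_pos: int | None = None  # 1-based leftmost position, None = unaligned


@dataclass(frozen=True)
class MtVariantCall:
    position: int
    ref: str
    alt: str
    heteroplasmy: float
    depth: int
    known_pathogenic: bool
    passed_cutoff: bool
    label: str = ""


@dataclass(frozen=True)
class MtDeletionCall:
    b5: int  # last retained base before the deleted segment (1-based)
    b3: int  # first retained base after it
    supporting_reads: int
    single_or_multiple: str = "single"

    @property
    def size(self) -> int:
        return self.b3 - self.b5 - 1


@dataclass(frozen=True)
class CopyNumberResult:
    ratio: float  # patient mt/nuclear copy-number ratio
    percent_of_control: float
    depleted: bool


@dataclass(frozen=True)
class MtDiagnosis:
    outcome: str  # solved_point | solved_single_deletion | escalate_to_wes | negative
    point_calls: tuple[MtVariantCall, ...] = ()
    deletions: tuple[MtDeletionCall, ...] = ()
    copy_number: CopyNumberResult | None = None


def call_point_variants(
    pileups,
    known_table: dict[tuple[int, str, str], dict],
    known_cutoff: float = KNOWN_CUTOFF,
    novel_cutoff: float = NOVEL_CUTOFF,
) -> list[MtVariantCall]:
    """Call point variants and small indels with heteroplasmy levels.

    D-loop positions are excluded (with a notice when one carries non-
    reference reads); zero-depth sites are skipped with a warning.  A call
    passes when its heteroplasmy reaches the known-pathogenic cutoff
    (default 2%) for table alleles and the general cutoff (default 5%)
    otherwise.  Output is sorted by position and independent of pileup
    order.
    """
    calls = []
    for pile in pileups:
        if not 1 <= pile.position <= MT_LENGTH:
            raise ValueError(f"position {pile.position} outside 1..{MT_LENGTH}")
        alt_alleles = [a for a, d in pile.depths.items() if a != pile.ref and d > 0]
        if in_dloop(pile.position):
            if alt_alleles:
                warnings.warn(
                    f"position {pile.position} is in the excluded D-loop region",
                    stacklevel=2,
                )
            continue
        total = pile.total_depth
        if total == 0:
            warnings.warn(f"zero depth at position {pile.position}; site skipped", stacklevel=2)
            continue
        for alt in alt_alleles:
            h = pile.depths[alt] / total
            entry = known_table.get((pile.position, pile.ref, alt))
            cutoff = known_cutoff if entry is not None else novel_cutoff
            calls.append(
                MtVariantCall(
                    position=pile.position,
                    ref=pile.ref,
                    alt=alt,
                    heteroplasmy=h,
                    depth=total,
                    known_pathogenic=entry is not None,
                    passed_cutoff=h >= cutoff,
                    label=entry["label"] if entry else "",
                )
            )
    calls.sort(key=lambda c: (c.position, c.alt))
    return calls


# ---------------------------------------------------------------------------
# deletion breakpoint placement


def _max_prefix_match(read: str, ref2: str, start: int) -> int:
    n = 0
    limit = min(len(read), len(ref2) - start)
    while n < limit and read[n] == ref2[start + n]:
        n += 1
    return n


def _find_arm(segment: str, ref2: str, anchor: int):
    """All (start, match_length) of maximal exact matches of segment's first
    ``anchor`` bases in the doubled reference, extended as far as possible."""
    seed = segment[:anchor]
    hits = []
    idx = ref2.find(seed)
    while idx != -1:
        hits.append((idx, _max_prefix_match(segment, ref2, idx)))
        idx = ref2.find(seed, idx + 1)
    return hits


def split_align_read(read: str, reference: str, anchor: int = MIN_ANCHOR):
    """Place a junction-spanning read on the reference.

    Returns the leftmost-normalised (b5, b3) 1-based junction, or None when
    the read aligns contiguously (no junction) or cannot be anchored with
    ``anchor`` exactly matching bases on both sides.  Direct repeats at the
    junction make a range of split points equivalent; the minimal-prefix
    split is chosen, which is the leftmost representation.
    """
    L = len(read)
    if L < 2 * anchor:
        return None
    ref2 = reference + reference  # circular genome: doubled linear sequence
    n = len(reference)
    prefix_hits = _find_arm(read, ref2, anchor)
    if not prefix_hits:
        return None
    rc_read = read[::-1]
    rc_ref2 = ref2[::-1]
    suffix_hits_rev = _find_arm(rc_read, rc_ref2, anchor)

    best = None
    for p_start, p_len in prefix_hits:
        if p_len >= L:
            return None  # contiguous reference read
        for s_start_rev, s_len in suffix_hits_rev:
            if s_len >= L:
                return None  # contiguous reference read
            if p_len + s_len < L:
                continue  # arms do not cover the read
            # suffix arm in forward coordinates: read[L-s_len:] matches
            # ref2[s_end-s_len+1 .. s_end] where s_end = len(ref2)-1-s_start_rev
            s_end = len(ref2) - 1 - s_start_rev
            s_begin = s_end - s_len + 1
            # Split points t in [L-s_len, p_len] are sequence-equivalent
            # (direct repeat); the minimal prefix is the leftmost junction.
            t = L - s_len
            b5_0 = p_start + t - 1  # 0-based last retained prefix base
            b3_0 = s_begin  # 0-based first retained suffix base at minimal t
            b5 = b5_0 % n + 1
            b3 = b3_0 % n + 1
            if b3 <= b5:
                continue
            size = b3 - b5 - 1
            if size <= 0:
                continue
            cand = (b5, b3, p_len + s_len)
            if best is None or cand[2] > best[2] or (cand[2] == best[2] and cand < best):
                best = cand
    if best is None:
        return None
    return best[0], best[1]


def detect_deletions(
    reads,
    reference: str,
    min_support: int = DEFAULT_MIN_SUPPORT,
    anchor: int = MIN_ANCHOR,
) -> list[MtDeletionCall]:
    """Detect large deletions from junction-spanning (unaligned) reads.

    Each unaligned read is split-aligned; identical normalised junctions are
    pooled, and events supported by at least ``min_support`` reads are
    reported sorted by breakpoint.  More than one distinct event marks the
    sample as carrying multiple deletions.  No junction reads is an empty
    result, not an error; reads shorter than two anchors are skipped.
    """
    if len(reference) != MT_LENGTH:
        raise ValueError(f"reference length {len(reference)} != {MT_LENGTH}")
    support: dict[tuple[int, int], int] = {}
    for read in reads:
        if read.aligned_pos is not None:
            continue
        junction = split_align_read(read.sequence, reference, anchor=anchor)
        if junction is not None:
            support[junction] = support.get(junction, 0) + 1
    events = sorted((j, c) for j, c in support.items() if c >= min_support)
    kind = "multiple" if len(events) > 1 else "single"
    return [
        MtDeletionCall(b5=b5, b3=b3, supporting_reads=c, single_or_multiple=kind)
        for (b5, b3), c in events
    ]


def assess_copy_number(
    ratio: float,
    control_ratios,
    threshold: float = DEFAULT_DEPLETION_THRESHOLD,
) -> CopyNumberResult:
    """Normalise a patient mt/nuclear qPCR ratio to the control mean.

    ``ratio`` is the patient's mtDNA-target over nuclear-target copy-number
    ratio (e.g. ND1 normalised to B2M); percent = ratio / mean(controls) x
    100, and the sample is depleted when the percent falls below
    ``threshold`` (default 35%, capturing the 10-30% range typical of
    depletion syndromes).
    """
    controls = list(control_ratios)
    if not controls:
        raise ValueError("at least one control ratio is required")
    if ratio <= 0 or any(c <= 0 for c in controls):
        raise ValueError("copy-number ratios must be positive")
    percent = ratio / (sum(controls) / len(controls)) * 100.0
    return CopyNumberResult(ratio=ratio, percent_of_control=percent, depleted=percent < threshold)


def classify_mt_findings(
    calls,
    deletions,
    copy_number: CopyNumberResult | None = None,
) -> MtDiagnosis:
    """Combine the three callers into the mtDNA-stage outcome.

    Multiple distinct deletions or depletion always escalate to exome
    analysis (nuclear maintenance defect suspected); otherwise a passing
    known-pathogenic point variant solves the family, a single large
    deletion solves it, and anything else is negative (and proceeds to the
    exome stage in the pipeline).
    """
    calls = tuple(calls)
    deletions = tuple(deletions)
    passing_known = tuple(c for c in calls if c.known_pathogenic and c.passed_cutoff)
    depleted = copy_number is not None and copy_number.depleted
    if len(deletions) > 1 or depleted:
        outcome = "escalate_to_wes"
    elif passing_known:
        outcome = "solved_point"
    elif len(deletions) == 1:
        outcome = "solved_single_deletion"
    else:
        outcome = "negative"
    return MtDiagnosis(
        outcome=outcome, point_calls=calls, deletions=deletions, copy_number=copy_number
    )
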