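"""Runs of homozygosity/hemizygosity from biallelic genotype tracks.

A run is a maximal stretch of markers without disallowed heterozygous calls
(missing calls never break a run); its physical length is the distance
between its first and last marker, and only runs of at least the configured
cutoff (default 5 Mb, the criterion used for consanguineous-family mapping)
are reported.  In consanguineous families such runs flag the genomic
neighbourhoods most likely to harbour a recessive homozygous causal variant.

With ``het_tolerance`` 0 (the default; simulated tracks are error-free) the
reported runs are exactly the maximal qualifying windows.  With a positive
tolerance the scan is greedy left-to-right: a run is closed at the
(tolerance+1)-th heterozygous call and the next run starts after it, so
reported runs are always disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass

GENOTYPES = {"hom_ref", "het", "hom_alt", "hemi", "missing"}

DEFAULT_CUTOFF_BP = 5_000_000


@dataclass(frozen=True)
class ROHRegion:
    chromosome: str
    start: int  # 1-based inclusive (first marker of the run)
    end: int  # 1-based inclusive (last marker of the run)
    member_id: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, chromosome: str, position: int) -> bool:
        return self.chromosome == chromosome and self.start <= position <= self.end


def detect_roh(
    track,
    cutoff: int = DEFAULT_CUTOFF_BP,
    het_tolerance: int = 0,
    member_id: str = "",
) -> list[ROHRegion]:
    """Detect runs of homozygosity of at least ``cutoff`` bp.

    ``track`` is an iterable of (chromosome, position, genotype) tuples
    sorted by position within each chromosome, with genotypes drawn from
    {hom_ref, het, hom_alt, hemi, missing}.  An unsorted track or an unknown
    genotype is an input error.  Runs may not start or end on a tolerated
    heterozygous call; returned regions are non-overlapping and sorted.
    """
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for chrom, pos, gt in track:
        if gt not in GENOTYPES:
            raise ValueError(f"unknown genotype {gt!r} at {chrom}:{pos}")
        lane = by_chrom.setdefault(str(chrom), [])
        if lane and pos <= lane[-1][0]:
            raise ValueError(f"track not sorted at {chrom}:{pos}")
        lane.append((int(pos), gt))

    regions: list[ROHRegion] = []
    for chrom, lane in by_chrom.items():
        informative = [(pos, gt) for pos, gt in lane if gt != "missing"]
        run: list[tuple[int, str]] = []
        hets = 0
        for pos, gt in informative + [(None, "het")] * (het_tolerance + 1):
            if gt == "het":
                hets += 1
            if gt == "het" and hets > het_tolerance:
                _emit(regions, chrom, run, cutoff, member_id)
                run, hets = [], 0
            else:
                run.append((pos, gt))
    regions.sort(key=lambda r: (r.chromosome, r.start))
    return regions


def _emit(regions, chrom, run, cutoff, member_id) -> None:
    # trim tolerated het calls from the run edges
    lo, hi = 0, len(run) - 1
    while lo <= hi and run[lo][1] == "het":
        lo += 1
    while hi >= lo and run[hi][1] == "het":
        hi -= 1
    if lo > hi:
        return
    start, end = run[lo][0], run[hi][0]
    if end - start + 1 >= cutoff:
        regions.append(ROHRegion(chrom, start, end, member_id))


def write_bed(regions: list[ROHRegion], path) -> None:
    """Write regions as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for r in regions:
            name = r.member_id or "."
            fh.write(f"{r.chromosome}\t{r.start - 1}\t{r.end}\t{name}\n")
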