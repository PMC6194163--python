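"""File-format bridges: VCF, FASTA read sets, genotype tracks, qPCR TSV.

The pipeline operates on in-memory records; these writers/readers connect
it to the standard interchange formats.  VCF output is v4.2 text:
mtDNA variants carry the allele fraction (FORMAT AF) and large deletions
are symbolic <DEL> records with END and SVLEN; family exome VCFs carry
one GT column per member plus the annotation fields the filter consumes.
"""

from __future__ import annotations

import json

from .cohort import FamilySpec
from .mtdna import MtRead
from .refseq import mt_reference
from .wes import FamilyGenotypes, NuclearVariant

_GT_CODE = {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1", "hemi": "1", "missing": "./."}
_CODE_GT = {v: k for k, v in _GT_CODE.items()} | {"0|1": "het", "1|1": "hom_alt", "0/0": "hom_ref"}


def write_mt_vcf(calls, deletions, path) -> None:
    """Write mtDNA point calls (FORMAT AF = heteroplasmy) and deletion
    calls (symbolic <DEL> with END/SVLEN) as VCF v4.2."""
    ref = mt_reference()
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=chrM,length=16569>",
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End of deleted interval">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Deleted length">',
        '##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Junction reads">',
        '##INFO=<ID=KNOWN,Number=0,Type=Flag,Description="Known pathogenic allele">',
        '##FORMAT=<ID=AF,Number=1,Type=Float,Description="Heteroplasmy (allele fraction)">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE",
    ]
    records = []
    for c in calls:
        info = "KNOWN" if c.known_pathogenic else "."
        filt = "PASS" if c.passed_cutoff else "lowAF"
        records.append(
            (c.position, f"chrM\t{c.position}\t.\t{c.ref}\t{c.alt}\t.\t{filt}\t{info}"
             f"\tAF:DP\t{c.heteroplasmy:.4f}:{c.depth}")
        )
    for d in deletions:
        pos = d.b5
        info = f"END={d.b3 - 1};SVLEN=-{d.size};SUPPORT={d.supporting_reads}"
        records.append(
            (pos, f"chrM\t{pos}\t.\t{ref[pos - 1]}\t<DEL>\t.\tPASS\t{info}\tAF:DP\t.:.")
        )
    records.sort()
    with open(path, "w") as fh:
        fh.write("\n".join(lines + [r[1] for r in records]) + "\n")


def write_family_vcf(
    family: FamilySpec, variants, genotypes: FamilyGenotypes, path
) -> None:
    """Write a per-family exome VCF (v4.2, one GT column per member) with
    the annotation fields the filter cascade consumes in INFO."""
    members = [m.member_id for m in family.members]
    lines = [
        "##fileformat=VCFv4.2",
        *[f"##contig=<ID={c}>" for c in [str(i) for i in range(1, 23)] + ["X"]],
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=EFFECT,Number=1,Type=String,Description="Effect class">',
        '##INFO=<ID=POPAF,Number=1,Type=Float,Description="Population allele frequency">',
        '##INFO=<ID=IHAF,Number=1,Type=Float,Description="In-house allele frequency">',
        '##INFO=<ID=NDMG,Number=1,Type=Integer,Description="Damaging predictor calls (of 4)">',
        '##INFO=<ID=ACMG,Number=1,Type=Integer,Description="Variant class 1-5">',
        '##INFO=<ID=MITO,Number=0,Type=Flag,Description="MitoCarta panel member">',
        '##INFO=<ID=OMIMAD,Number=0,Type=Flag,Description="OMIM dominant-disease gene">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(members),
    ]
    recs = []
    for v in sorted(variants, key=lambda v: (v.chromosome, v.position, v.alt)):
        info = [
            f"GENE={v.gene}", f"EFFECT={v.effect}",
            f"IHAF={v.inhouse_af:.5f}", f"NDMG={v.n_damaging}", f"ACMG={v.acmg_class}",
        ]
        if v.population_af is not None:
            info.insert(2, f"POPAF={v.population_af:.5f}")
        if v.mitocarta:
            info.append("MITO")
        if v.omim_dominant:
            info.append("OMIMAD")
        gts = "\t".join(
            _GT_CODE[genotypes.get(v.variant_id, {}).get(m, "missing")] for m in members
        )
        recs.append(f"{v.chromosome}\t{v.position}\t{v.variant_id}\t{v.ref}\t{v.alt}\t.\tPASS\t"
                    + ";".join(info) + f"\tGT\t{gts}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines + recs) + "\n")


def read_family_vcf(path) -> tuple[list[NuclearVariant], FamilyGenotypes, list[str]]:
    """Read a family exome VCF written by :func:`write_family_vcf` back into
    variant records and per-member genotypes (cyvcf2-backed)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    members = list(vcf.samples)
    variants: list[NuclearVariant] = []
    genotypes: FamilyGenotypes = {}
    for rec in vcf:
        vid = rec.ID
        v = NuclearVariant(
            variant_id=vid,
            gene=rec.INFO.get("GENE"),
            chromosome=rec.CHROM,
            position=rec.POS,
            ref=rec.REF,
            alt=rec.ALT[0],
            effect=rec.INFO.get("EFFECT"),
            population_af=rec.INFO.get("POPAF"),
            inhouse_af=rec.INFO.get("IHAF"),
            n_damaging=rec.INFO.get("NDMG"),
            acmg_class=rec.INFO.get("ACMG"),
            mitocarta=rec.INFO.get("MITO") is not None,
            omim_dominant=rec.INFO.get("OMIMAD") is not None,
        )
        variants.append(v)
        codes = []
        for gt in rec.genotypes:
            alleles = gt[:-1]
            if all(a == -1 for a in alleles):
                codes.append("missing")
            elif len(alleles) == 1:
                codes.append("hemi" if alleles[0] == 1 else "hom_ref")
            elif sum(alleles) == 0:
                codes.append("hom_ref")
            elif sum(alleles) == 1:
                codes.append("het")
            else:
                codes.append("hom_alt")
        genotypes[vid] = dict(zip(members, codes))
    return variants, genotypes, members


def write_reads_fasta(reads, fasta_path, truth_path=None, truth: dict | None = None) -> None:
    """Write a read set as FASTA (aligned position recorded in the header;
    junction reads marked unaligned) with an optional truth sidecar JSON."""
    with open(fasta_path, "w") as fh:
        for r in reads:
            tag = f"pos={r.aligned_pos}" if r.aligned_pos is not None else "unaligned"
            fh.write(f">{r.name} {tag}\n{r.sequence}\n")
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            json.dump(truth or {}, fh, indent=1)


def read_reads_fasta(path) -> list[MtRead]:
    reads = []
    name = tag = None
    seq: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    reads.append(_mk_read(name, tag, "".join(seq)))
                head = line[1:].split()
                name, tag = head[0], head[1] if len(head) > 1 else "unaligned"
                seq = []
            else:
                seq.append(line)
    if name is not None:
        reads.append(_mk_read(name, tag, "".join(seq)))
    return reads


def _mk_read(name, tag, seq) -> MtRead:
    pos = int(tag.split("=")[1]) if tag and tag.startswith("pos=") else None
    return MtRead(name, seq, pos)


def write_track_tsv(track, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tgenotype\n")
        for chrom, pos, gt in track:
            fh.write(f"{chrom}\t{pos}\t{gt}\n")


def read_track_tsv(path):
    rows = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            chrom, pos, gt = line.rstrip("\n").split("\t")
            rows.append((chrom, int(pos), gt))
    return rows


def write_qpcr_tsv(ratio: float, controls, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tmt_nuclear_ratio\n")
        fh.write(f"patient\t{ratio:.6f}\n")
        for i, c in enumerate(controls, 1):
            fh.write(f"control_{i}\t{c:.6f}\n")
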