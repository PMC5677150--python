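"""File-format helpers: FASTA, event tables (TSV and a minimal VCF
dialect), per-gene alignment directories, and newick trees.

The VCF dialect is a small v4.2 subset: CHROM, POS, REF, ALT and one
column per strain whose genotype marks presence (1) or absence (0) of
the alternate allele. Pure insertions/deletions are written with the
conventional anchor base so POS/REF/ALT round-trip through standard
tools; the in-memory representation stays anchor-free (see events).
"""

from __future__ import annotations

import os
from typing import Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .events import Event, dataframe_to_events, events_to_dataframe


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, seqs: Mapping[str, str]):
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_events_tsv(events: Sequence[Event], path):
    events_to_dataframe(events).to_csv(path, sep="\t", index=False)


def read_events_tsv(path, ref: Optional[Mapping[str, str]] = None,
                    flank: int = 300) -> list[Event]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     dtype={"ref_allele": str, "alt_allele": str, "strains": str})
    return dataframe_to_events(df, ref=ref, flank=flank)


# ---------------------------------------------------------------------------
# minimal VCF dialect
# ---------------------------------------------------------------------------


def _anchored(ev: Event, ref: Mapping[str, str]):
    """(pos, ref, alt) with the VCF anchor base for pure indels."""
    if ev.ref_allele and ev.alt_allele:
        return ev.pos, ev.ref_allele, ev.alt_allele
    seq = ref[ev.chrom]
    if ev.pos > 1:
        anchor = seq[ev.pos - 2]
        return ev.pos - 1, anchor + ev.ref_allele, anchor + ev.alt_allele
    anchor = seq[ev.pos - 1 + len(ev.ref_allele)]
    return ev.pos, ev.ref_allele + anchor, ev.alt_allele + anchor


def write_vcf(events: Sequence[Event], ref: Mapping[str, str], path,
              samples: Optional[Sequence[str]] = None):
    if samples is None:
        samples = sorted({s for ev in events for s in ev.strains_with_alt})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, seq in ref.items():
            fh.write(f"##contig=<ID={chrom},length={len(seq)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for ev in sorted(events, key=lambda e: (e.chrom, e.pos)):
            pos, ra, aa = _anchored(ev, ref)
            gts = ["1" if s in ev.strains_with_alt else "0" for s in samples]
            fh.write(f"{ev.chrom}\t{pos}\t.\t{ra}\t{aa}\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")


def read_vcf(path, ref: Optional[Mapping[str, str]] = None,
             flank: int = 300) -> list[Event]:
    """Read the minimal VCF dialect back into anchor-free events."""
    from .events import left_align_indel

    samples: list[str] = []
    out: list[Event] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            f = line.split("\t")
            chrom, pos, ra, aa = f[0], int(f[1]), f[3], f[4]
            gts = f[9:]
            strains = frozenset(
                s for s, g in zip(samples, gts) if g.split(":")[0] not in ("0", ".", "0/0", "0|0")
            )
            # strip the anchor base shared by REF and ALT
            while ra and aa and ra[0] == aa[0]:
                ra, aa = ra[1:], aa[1:]
                pos += 1
            while ra and aa and ra[-1] == aa[-1]:
                ra, aa = ra[:-1], aa[:-1]
            if ref is not None and chrom in ref and (not ra or not aa):
                pos, ra, aa = left_align_indel(ref[chrom], pos, ra, aa)
            if not ra and not aa:
                continue
            if not ra or not aa:
                etype = "insertion" if not ra else "deletion"
            elif len(ra) == 1 and len(aa) == 1:
                etype = "snp"
            elif len(ra) == len(aa):
                etype = "snp_cluster"
            else:
                etype = "mixed"
            fl = fr = ""
            if ref is not None and chrom in ref:
                seq = ref[chrom]
                i = pos - 1
                fl = seq[max(0, i - flank) : i]
                fr = seq[i + len(ra) : i + len(ra) + flank]
            out.append(Event(chrom, pos, ra, aa, strains, etype,
                             flank_left=fl, flank_right=fr))
    return out


# ---------------------------------------------------------------------------
# alignments and trees
# ---------------------------------------------------------------------------


def read_msa_dir(path) -> dict[str, dict[str, str]]:
    """Read a directory of per-gene aligned FASTA files."""
    out = {}
    for name in sorted(os.listdir(path)):
        if name.endswith((".fa", ".fasta", ".fna", ".aln")):
            gene = name.rsplit(".", 1)[0]
            out[gene] = read_fasta(os.path.join(path, name))
    return out


def write_msa_dir(path, msas: Mapping[str, Mapping[str, str]]):
    os.makedirs(path, exist_ok=True)
    for gene, rows in msas.items():
        write_fasta(os.path.join(path, f"{gene}.fasta"), rows)
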