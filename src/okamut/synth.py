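"""Synthetic genomes, strain cohorts and phylogenetic datasets with full
truth labels.

The generator emulates the structure of a haploid yeast
mutation-accumulation experiment: a toy reference seeded with simple
sequence repeats, direct-repeat (ABA / ABABA) structures and perfect or
quasi palindromes; two lines of strains passaged through subculture
bottlenecks (samples at subculture 0, 5 and 25); and per-mechanism
mutation processes (slippage, direct-repeat duplication/deletion,
fold-back template switching, background SNPs) applied along the lineage
so that shared-ancestry changes and recurrent hotspot loci arise
naturally. Everything is deterministic under the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from ._seq import revcomp
from .errors import DesignError
from .events import StrainSet, left_align_indel
from .repeats import (
    decompose_direct_repeat,
    find_inverted_repeats,
    find_quasi_palindromes,
)
from .switch import (
    make_correction_model,
    make_expansion_model,
    simulate_switch,
)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class GenomeDesign:
    """Layout of a toy reference genome with planted repeat features."""

    n_chroms: int = 4
    chrom_len: int = 250_000
    gc: float = 0.38                  # yeast-like base composition
    telomere_margin: int = 20_000     # features stay clear of chromosome ends
    min_feature_gap: int = 300
    n_ssr: int = 120
    n_aba: int = 120
    n_palindrome: int = 30
    n_quasi: int = 30
    ssr_unit_len: tuple[int, int] = (1, 4)
    ssr_copies: tuple[int, int] = (6, 14)
    aba_len_A: tuple[int, int] = (4, 12)
    aba_len_B: tuple[int, int] = (6, 30)
    palindrome_arm: tuple[int, int] = (8, 16)
    palindrome_spacer: tuple[int, int] = (3, 8)
    # >= 2 arm edits: a single corrected mismatch yields an isolated SNP,
    # which is not identifiable as a template-switch product
    quasi_arm_edits: tuple[int, int] = (2, 3)
    n_hotspots: int = 6
    seed: int = 0


@dataclass(frozen=True)
class MutationConfig:
    """Per-mechanism mutation process for the strain cohort.

    Rates are per eligible feature per generation; the defaults are
    proportioned so a default cohort echoes the observed class mix
    (SSR : direct repeat : template switch of roughly 183 : 177 : 21).
    """

    n_lines: int = 2
    n_strains_per_line: int = 5
    shared_generations: int = 5      # subculture 0 -> 5 (control branch)
    private_generations: int = 20    # subculture 5 -> 25
    ssr_rate: float = 7.6e-3
    dr_rate: float = 7.4e-3
    switch_rate: float = 1.75e-3
    background_snp_rate: float = 1.5e-7  # per bp per generation per lineage
    insertion_bias: float = 0.67     # P(insertion) for slippage/direct-repeat
    hotspot_multiplier: float = 10.0
    self_len_range: tuple[int, int] = (10, 60)
    amplification_range: tuple[int, int] = (5, 20)
    resection_range: tuple[int, int] = (5, 17)
    seed: int = 0


@dataclass
class Cohort:
    ref: dict                        # chrom -> sequence
    msas: dict                       # chrom -> {row id: aligned sequence}
    truth: pd.DataFrame              # per-strain event truth labels
    focal: list                      # StrainSet per line (subculture 25)
    controls: list                   # StrainSet for subculture 0 and 5
    ref_id: str = "reference"


@dataclass
class PhyloDataset:
    tree: str                        # newick
    msas: dict                       # gene -> {taxon: aligned sequence}
    cds: dict                        # gene -> focal-taxon sequence
    truth: pd.DataFrame              # per planted locus switch-move truth
    focal_taxon: str = "Scer"


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def _primitive_unit(rng: np.random.Generator, k: int) -> str:
    while True:
        u = "".join(_BASES[rng.integers(0, 4, size=k)])
        if all(u != u[p:] + u[:p] for p in range(1, k)):
            return u


def _stamp(seq: list, start0: int, payload: str):
    seq[start0 : start0 + len(payload)] = list(payload)


def _verify_ssr(s: str, start0: int, unit: str, copies: int) -> bool:
    p = len(unit)
    end0 = start0 + p * copies
    if s[start0:end0] != unit * copies:
        return False
    if start0 > 0 and s[start0 - 1] == unit[-1]:
        return False
    if end0 < len(s) and s[end0] == s[end0 - p]:
        return False
    return True


class _ProbeEvent:
    """Duck-typed event used to verify a planted ABA structure."""

    def __init__(self, pos, ref_allele, alt_allele, flank_left, flank_right, etype):
        self.pos = pos
        self.ref_allele = ref_allele
        self.alt_allele = alt_allele
        self.flank_left = flank_left
        self.flank_right = flank_right
        self.event_type = etype


def _verify_aba(s: str, start0: int, A: str, B: str, copies: int) -> bool:
    """The planted (AB)^k A structure must support a clean direct-repeat
    decomposition and must not read as a micro-satellite."""
    unit = A + B
    body = unit * copies + A
    end0 = start0 + len(body)
    if s[start0:end0] != body:
        return False
    probe = _ProbeEvent(
        pos=end0 + 1,
        ref_allele="",
        alt_allele=B + A,
        flank_left=s[max(0, start0 - 80) : end0],
        flank_right=s[end0 : end0 + 80],
        etype="insertion",
    )
    dec = decompose_direct_repeat(probe)
    if dec is None or dec.similarity < 1.0:
        return False
    # must not be explainable as a short-period tandem tract
    for p in range(1, 7):
        if len(unit) % p == 0 and unit == unit[:p] * (len(unit) // p):
            return False
    return True


def _verify_palindrome(s: str, start0: int, arm: int, spacer: int) -> bool:
    """Planted IR must be recovered exactly (no accidental arm extension)
    and no equally long competing IR may overlap its footprint."""
    w0 = max(0, start0 - 25)
    end0 = start0 + 2 * arm + spacer
    window = s[w0 : end0 + 25]
    irs = find_inverted_repeats(window, min_arm=5, max_spacer=70, min_loop=3)
    target = [
        r for r in irs
        if r.left_start == start0 - w0 + 1 and r.arm_len == arm and r.spacer_len == spacer
    ]
    if len(target) != 1:
        return False
    rivals = [
        r for r in irs
        if r is not target[0]
        and r.arm_len >= arm
        and r.right_end >= start0 - w0 + 1
        and r.left_start <= end0 - w0
    ]
    return not rivals


def _verify_quasi(s: str, start0: int, arm_left: str, spacer: int,
                  arm_right: str, edits: int) -> bool:
    w0 = max(0, start0 - 25)
    span = len(arm_left) + spacer + len(arm_right)
    end0 = start0 + span
    window = s[w0 : end0 + 25]
    # no perfect IR as long as the planted arms may overlap the footprint
    for r in find_inverted_repeats(window, min_arm=5, max_spacer=70):
        if (r.arm_len >= len(arm_left)
                and r.right_end >= start0 - w0 + 1
                and r.left_start <= end0 - w0):
            return False
    qs = find_quasi_palindromes(window, min_arm=5, max_spacer=70, max_arm_edits=3)
    return any(
        q.left_start == start0 - w0 + 1 and q.arm_edits == edits for q in qs
    )


def make_genome(design: GenomeDesign) -> tuple[dict, pd.DataFrame]:
    """Build the reference and its feature truth table.

    Every planted feature is verified with the repeat scanners after
    stamping (palindromes are found with the designed arm/spacer, quasi
    palindromes carry exactly the designed arm-edit count, tracts are
    pure and maximal); colliding placements are redrawn.
    """
    rng = np.random.default_rng(design.seed)
    n_features = design.n_ssr + design.n_aba + design.n_palindrome + design.n_quasi
    usable = design.n_chroms * (design.chrom_len - 2 * design.telomere_margin)
    if n_features * (design.min_feature_gap + 120) > usable:
        raise DesignError("planted features exceed non-telomeric territory")

    chroms = {f"chr{i+1}": list(_random_seq(rng, design.chrom_len, design.gc))
              for i in range(design.n_chroms)}
    kinds = (["ssr"] * design.n_ssr + ["aba"] * design.n_aba
             + ["palindrome"] * design.n_palindrome + ["quasi"] * design.n_quasi)
    rng.shuffle(kinds)

    # evenly spaced slots with jitter, round-robin across chromosomes
    per_chrom = -(-n_features // design.n_chroms)
    slots = []
    for ci, chrom in enumerate(chroms):
        span = design.chrom_len - 2 * design.telomere_margin
        step = span // (per_chrom + 1)
        for k in range(per_chrom):
            base = design.telomere_margin + (k + 1) * step
            slots.append((chrom, base + int(rng.integers(-step // 4, step // 4 + 1))))
    rng.shuffle(slots)

    rows = []
    hot_ids = set(rng.choice(n_features, size=min(design.n_hotspots, n_features),
                             replace=False).tolist())
    for fid, (kind, (chrom, start0)) in enumerate(zip(kinds, slots)):
        s = chroms[chrom]
        ok = False
        for _try in range(40):
            if kind == "ssr":
                p = int(rng.integers(design.ssr_unit_len[0], design.ssr_unit_len[1] + 1))
                copies = int(rng.integers(design.ssr_copies[0], design.ssr_copies[1] + 1))
                unit = _primitive_unit(rng, p)
                _stamp(s, start0, unit * copies)
                if _verify_ssr("".join(s[start0 - 30 : start0 + p * copies + 30]),
                               30, unit, copies):
                    rows.append(dict(feature_id=fid, chrom=chrom, start=start0 + 1,
                                     end=start0 + p * copies, ftype="ssr",
                                     unit=unit, copies=copies))
                    ok = True
            elif kind == "aba":
                la = int(rng.integers(design.aba_len_A[0], design.aba_len_A[1] + 1))
                lb = int(rng.integers(design.aba_len_B[0], design.aba_len_B[1] + 1))
                copies = int(rng.integers(1, 3))  # ABA or ABABA
                A = _primitive_unit(rng, la)
                B = "".join(_BASES[rng.integers(0, 4, size=lb)])
                body = (A + B) * copies + A
                _stamp(s, start0, body)
                win = "".join(s[max(0, start0 - 100) : start0 + len(body) + 100])
                if _verify_aba(win, start0 - max(0, start0 - 100), A, B, copies):
                    rows.append(dict(feature_id=fid, chrom=chrom, start=start0 + 1,
                                     end=start0 + len(body), ftype="aba",
                                     unit=A, copies=copies, len_A=la, len_B=lb,
                                     B=B))
                    ok = True
            elif kind == "palindrome":
                arm = int(rng.integers(design.palindrome_arm[0], design.palindrome_arm[1] + 1))
                sp = int(rng.integers(design.palindrome_spacer[0], design.palindrome_spacer[1] + 1))
                left = "".join(_BASES[rng.integers(0, 4, size=arm)])
                body = left + "".join(_BASES[rng.integers(0, 4, size=sp)]) + revcomp(left)
                _stamp(s, start0, body)
                win0 = max(0, start0 - 25)
                if _verify_palindrome("".join(s[win0 : start0 + len(body) + 25]),
                                      start0 - win0, arm, sp):
                    rows.append(dict(feature_id=fid, chrom=chrom, start=start0 + 1,
                                     end=start0 + len(body), ftype="palindrome",
                                     arm_len=arm, spacer_len=sp))
                    ok = True
            else:  # quasi palindrome
                arm = int(rng.integers(design.palindrome_arm[0], design.palindrome_arm[1] + 1))
                sp = int(rng.integers(design.palindrome_spacer[0], design.palindrome_spacer[1] + 1))
                edits = int(rng.integers(design.quasi_arm_edits[0], design.quasi_arm_edits[1] + 1))
                left = "".join(_BASES[rng.integers(0, 4, size=arm)])
                right = list(revcomp(left))
                # damage the right arm interior with substitution edits
                positions = rng.choice(np.arange(1, arm - 1), size=edits, replace=False)
                for pmut in positions:
                    cur = right[pmut]
                    right[pmut] = str(rng.choice([b for b in "ACGT" if b != cur]))
                body = left + "".join(_BASES[rng.integers(0, 4, size=sp)]) + "".join(right)
                _stamp(s, start0, body)
                win0 = max(0, start0 - 25)
                if _verify_quasi("".join(s[win0 : start0 + len(body) + 25]),
                                 start0 - win0, left, sp, "".join(right), edits):
                    rows.append(dict(feature_id=fid, chrom=chrom, start=start0 + 1,
                                     end=start0 + len(body), ftype="quasi",
                                     arm_len=arm, spacer_len=sp, arm_edits=edits))
                    ok = True
            if ok:
                break
            # redraw the local background and try again
            _stamp(s, start0 - 20, _random_seq(rng, 140, design.gc))
        if not ok:
            raise DesignError(f"could not place feature {fid} ({kind}) on {chrom}")
    truth = pd.DataFrame(rows)
    truth["hotspot"] = truth["feature_id"].isin(hot_ids)
    ref = {c: "".join(s) for c, s in chroms.items()}
    return ref, truth


# ---------------------------------------------------------------------------
# cohort mutagenesis
# ---------------------------------------------------------------------------


def _normalize(ref_seq: str, pos: int, ra: str, aa: str):
    """Trim shared flanks, then left-align pure indels (canonical truth)."""
    while ra and aa and ra[-1] == aa[-1]:
        ra, aa = ra[:-1], aa[:-1]
    while ra and aa and ra[0] == aa[0]:
        ra, aa = ra[1:], aa[1:]
        pos += 1
    if not ra or not aa:
        pos, ra, aa = left_align_indel(ref_seq, pos, ra, aa)
    return pos, ra, aa


def _draw_event(feat, ref_seq: str, cfg: MutationConfig, rng: np.random.Generator):
    """One mechanism-specific mutation at a planted feature.

    Returns (pos, ref_allele, alt_allele, mech_class, direction, event_kind).
    """
    start0 = int(feat["start"]) - 1
    if feat["ftype"] == "ssr":
        unit = feat["unit"]
        insert = rng.random() < cfg.insertion_bias or int(feat["copies"]) < 3
        if insert:
            pos, ra, aa = _normalize(ref_seq, start0 + 1, "", unit)
            return pos, ra, aa, "ssr", "insertion"
        pos, ra, aa = _normalize(ref_seq, start0 + 1, unit, "")
        return pos, ra, aa, "ssr", "deletion"
    if feat["ftype"] == "aba":
        A, B = feat["unit"], feat["B"]
        copies = int(feat["copies"])
        insert = rng.random() < cfg.insertion_bias or copies < 2
        if insert:
            pos, ra, aa = _normalize(ref_seq, start0 + len(A) + 1, "", B + A)
            return pos, ra, aa, "direct_repeat", "insertion"
        pos, ra, aa = _normalize(ref_seq, start0 + len(A) + 1, B + A, "")
        return pos, ra, aa, "direct_repeat", "deletion"
    # template switching on (quasi-)palindromes: work in a local window
    w0 = max(0, start0 - 150)
    w1 = min(len(ref_seq), int(feat["end"]) + 150)
    window = ref_seq[w0:w1]
    f_lo = start0 - w0  # 0-based feature start in window
    if feat["ftype"] == "quasi":
        # detect in the same tight window used at planting time (wider
        # windows can prefer overlapping chance structure), then shift
        # coordinates into the simulation window
        t0 = max(0, f_lo - 25)
        tight = window[t0 : int(feat["end"]) - w0 + 25]
        qs = [q for q in find_quasi_palindromes(tight, min_arm=5, max_spacer=70,
                                                max_arm_edits=3)
              if q.left_start == f_lo - t0 + 1]
        if not qs:
            raise DesignError("planted quasi-palindrome not recoverable")
        from .repeats import InvertedRepeat

        q = qs[0]
        q = InvertedRepeat(
            left_start=q.left_start + t0, left_end=q.left_end + t0,
            right_start=q.right_start + t0, right_end=q.right_end + t0,
            arm_len=q.arm_len, spacer_len=q.spacer_len, arm_edits=q.arm_edits,
        )
        model = make_correction_model(q, correct_right=bool(rng.integers(0, 2)))
        mech = "quasi_palindrome_correction"
    else:
        irs = find_inverted_repeats(window, min_arm=5, max_spacer=70, min_loop=3)
        irs = [r for r in irs if r.left_start == f_lo + 1]
        if not irs:
            raise DesignError("planted palindrome not recoverable")
        ir = irs[0]
        sl = int(rng.integers(cfg.self_len_range[0], cfg.self_len_range[1] + 1))
        sl = min(sl, ir.left_start - 1)
        kind = rng.choice(["expansion", "amplified", "resected"])
        if kind == "expansion":
            model = make_expansion_model(ir, sl, ir.right_end + 1)
        elif kind == "amplified":
            amp = int(rng.integers(cfg.amplification_range[0],
                                   cfg.amplification_range[1] + 1))
            amp = min(amp, ir.right_end - 1)
            model = make_expansion_model(ir, sl, ir.right_end - amp + 1)
        else:
            res = int(rng.integers(cfg.resection_range[0], cfg.resection_range[1] + 1))
            res = min(res, len(window) - ir.right_end - 1)
            model = make_expansion_model(ir, sl, ir.right_end + res + 1,
                                         resected_len=res)
        mech = "palindrome_expansion"
    alt_window = simulate_switch(window, model)
    # express the window change as a reference-coordinate event
    cp = 0
    while cp < min(len(window), len(alt_window)) and window[cp] == alt_window[cp]:
        cp += 1
    cs = 0
    while (cs < min(len(window), len(alt_window)) - cp
           and window[len(window) - 1 - cs] == alt_window[len(alt_window) - 1 - cs]):
        cs += 1
    ra = window[cp : len(window) - cs]
    aa = alt_window[cp : len(alt_window) - cs]
    pos, ra, aa = _normalize(ref_seq, w0 + cp + 1, ra, aa)
    d = len(aa) - len(ra)
    direction = "insertion" if d > 0 else "deletion" if d < 0 else "unknown_mixed"
    return pos, ra, aa, mech, direction


_MECH_RATE = {"ssr": "ssr_rate", "aba": "dr_rate",
              "palindrome": "switch_rate", "quasi": "switch_rate"}


def mutate_strains(
    ref: dict, features: pd.DataFrame, cfg: MutationConfig
) -> Cohort:
    """Mutate a two-line cohort along its subculture lineage.

    Shared-branch mutations (subculture 0 -> 5) are inherited by the
    line's subculture-5 control and all its subculture-25 strains, so the
    control filter in event extraction is exercised; private mutations
    arise on each strain's own branch. Hotspot features mutate at an
    elevated rate and therefore recur across strains.
    """
    rng = np.random.default_rng(cfg.seed)
    lines = [f"L{i+1}" for i in range(cfg.n_lines)]
    focal_sets, control_sets = [], []
    strain_events: dict[str, list] = {}
    truth_rows = []

    for line in lines:
        zero_id = f"{line}-0"
        five_id = f"{line}-5"
        strains = [f"{line}-25.{k+1}" for k in range(cfg.n_strains_per_line)]
        focal_sets.append(StrainSet(line, 25, tuple(strains)))
        control_sets.append(StrainSet(line, 0, (zero_id,)))
        control_sets.append(StrainSet(line, 5, (five_id,)))
        for sid in [zero_id, five_id] + strains:
            strain_events[sid] = []

        for _, feat in features.iterrows():
            rate = getattr(cfg, _MECH_RATE[feat["ftype"]])
            if feat["hotspot"]:
                rate *= cfg.hotspot_multiplier
            ref_seq = ref[feat["chrom"]]
            carriers: list[tuple[list[str], str]] = []
            p_shared = 1.0 - np.exp(-rate * cfg.shared_generations)
            p_private = 1.0 - np.exp(-rate * cfg.private_generations)
            if rng.random() < p_shared:
                carriers.append(([five_id] + strains, "shared"))
            else:
                for sid in strains:
                    if rng.random() < p_private:
                        carriers.append(([sid], "private"))
            for who, branch in carriers:
                pos, ra, aa, mech, direction = _draw_event(feat, ref_seq, cfg, rng)
                for sid in who:
                    strain_events[sid].append((feat["chrom"], pos, ra, aa))
                truth_rows.append(dict(
                    chrom=feat["chrom"], pos=pos, ref_allele=ra, alt_allele=aa,
                    strains=";".join(s for s in who if s != five_id),
                    mech_class=mech, direction=direction, branch=branch,
                    feature_id=int(feat["feature_id"]),
                ))

    # background SNPs on the subculture-25 private branches, kept clear
    # of planted features and of each other so events never merge
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in ref}
    for _, feat in features.iterrows():
        occupied[feat["chrom"]].append((int(feat["start"]) - 60, int(feat["end"]) + 60))
    focal_ids = [s for fs in focal_sets for s in fs.strain_ids]
    for chrom, seq in sorted(ref.items()):
        lam = cfg.background_snp_rate * len(seq) * cfg.private_generations
        n_snps = rng.poisson(lam * len(focal_ids)) if lam > 0 else 0
        placed = attempts = 0
        while placed < n_snps and attempts < 50 * n_snps + 100:
            attempts += 1
            p0 = int(rng.integers(100, len(seq) - 100))
            if any(a <= p0 <= b for a, b in occupied[chrom]):
                continue
            occupied[chrom].append((p0 - 60, p0 + 60))
            sid = focal_ids[int(rng.integers(len(focal_ids)))]
            base = seq[p0]
            alt = str(rng.choice([b for b in "ACGT" if b != base]))
            strain_events[sid].append((chrom, p0 + 1, base, alt))
            truth_rows.append(dict(
                chrom=chrom, pos=p0 + 1, ref_allele=base, alt_allele=alt,
                strains=sid, mech_class="other", direction="unknown_mixed",
                branch="private", feature_id=-1,
            ))
            placed += 1

    truth = pd.DataFrame(
        truth_rows,
        columns=["chrom", "pos", "ref_allele", "alt_allele", "strains",
                 "mech_class", "direction", "branch", "feature_id"],
    ).sort_values(["chrom", "pos"]).reset_index(drop=True)
    msas = {c: _build_msa(ref[c], c, strain_events) for c in ref}
    return Cohort(ref=ref, msas=msas, truth=truth,
                  focal=focal_sets, controls=control_sets)


def _build_msa(ref_seq: str, chrom: str, strain_events: dict) -> dict:
    """Gapped alignment of all strains against the reference chromosome.

    Events at one locus are merged over the union of their reference
    spans; every strain's alternate block is left-justified and padded
    with gaps to the block width, which reproduces the column structure a
    profile aligner would emit for these simple loci.
    """
    # collect unique event keys for this chromosome
    keys: dict[tuple, set] = {}
    for sid, evs in strain_events.items():
        for (c, pos, ra, aa) in evs:
            if c == chrom:
                keys.setdefault((pos, ra, aa), set()).add(sid)
    # group into loci by reference-span overlap
    loci: list[list[tuple]] = []
    cur_end = -2
    for (pos, ra, aa) in sorted(keys):
        span_end = pos + len(ra) - 1  # pos-1 for insertions
        if loci and pos <= cur_end + 1:
            loci[-1].append((pos, ra, aa))
            cur_end = max(cur_end, span_end)
        else:
            loci.append([(pos, ra, aa)])
            cur_end = span_end
    rows = {sid: [] for sid in strain_events}
    ref_parts = []
    prev = 0  # 0-based cursor on reference
    for group in loci:
        s = min(p for p, _, _ in group)
        e = max(p + len(r) - 1 for p, r, _ in group)
        e = max(e, s - 1)
        ref_block = ref_seq[s - 1 : e]
        mid = ref_seq[prev : s - 1]
        alleles = {}
        for (pos, ra, aa) in group:
            full_alt = ref_seq[s - 1 : pos - 1] + aa + ref_seq[pos - 1 + len(ra) : e]
            for sid in keys[(pos, ra, aa)]:
                alleles[sid] = full_alt
        width = max([len(ref_block)] + [len(a) for a in alleles.values()])
        ref_parts.append(mid + ref_block.ljust(width, "-"))
        for sid in rows:
            a = alleles.get(sid, ref_block)
            rows[sid].append(mid + a.ljust(width, "-"))
        prev = e
    tail = ref_seq[prev:]
    msa = {sid: "".join(parts) + tail for sid, parts in rows.items()}
    msa["reference"] = "".join(ref_parts) + tail
    return msa


# ---------------------------------------------------------------------------
# phylogenetic datasets
# ---------------------------------------------------------------------------

DEFAULT_TREE = (
    "((((((Scer:0.06,Spar:0.06):0.03,Smik:0.09):0.02,Skud:0.11):0.01,"
    "Sarb:0.12):0.01,Suva:0.13):0.01,Seub:0.14);"
)


def make_phylo_dataset(
    tree: Optional[str] = None,
    n_genes: int = 20,
    gene_len: int = 240,
    arm_range: tuple[int, int] = (6, 10),
    spacer_range: tuple[int, int] = (0, 8),
    switch_rate: float = 0.0,
    kappa: float = 3.0,
    gc: float = 0.38,
    seed: int = 0,
) -> PhyloDataset:
    """Genes evolved down a phylogeny under HKY, with an optional
    quasi-palindrome-to-palindrome conversion move.

    Each gene carries one planted perfect palindrome at its centre. With
    ``switch_rate`` = 0 the dataset is a pure substitution-only null;
    with a positive rate, each planted locus may additionally undergo a
    template-switching move on any branch (a symmetric arm change plus
    re-homogenisation of the arms), which creates a new perfect IR form.
    Alignment is trivial (substitutions only), so the per-gene MSAs are
    the leaf sequences themselves.
    """
    import dendropy

    from ._seq import decode, encode
    from .evolution import _Evolver

    newick = tree or DEFAULT_TREE
    t = dendropy.Tree.get(data=newick, schema="newick")
    rng = np.random.default_rng(seed)
    freqs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    ev = _Evolver(t, kappa, freqs)
    leaf_names = [leaf.taxon.label for leaf in t.leaf_node_iter()]
    focal = "Scer" if "Scer" in leaf_names else leaf_names[0]

    msas, cds = {}, {}
    truth_rows = []
    for g in range(n_genes):
        gene = f"g{g+1:04d}"
        arm = int(rng.integers(arm_range[0], arm_range[1] + 1))
        sp = int(rng.integers(spacer_range[0], spacer_range[1] + 1))
        left = "".join(_BASES[rng.integers(0, 4, size=arm)])
        pal = left + "".join(_BASES[rng.integers(0, 4, size=sp)]) + revcomp(left)
        mid = gene_len // 2 - len(pal) // 2
        root = (_random_seq(rng, mid, gc) + pal
                + _random_seq(rng, gene_len - mid - len(pal), gc))
        lo, hi = mid, mid + len(pal)  # 0-based palindrome footprint

        states = {}
        n_moves = 0
        for node in t.preorder_node_iter():
            if node.parent_node is None:
                states[node] = encode(root)
                continue
            parent = states[node.parent_node]
            bl = node.edge.length or 0.0
            if bl <= 0:
                child = parent.copy()
            else:
                cum = ev._P(bl)
                u = rng.random(parent.size)
                child = np.empty_like(parent)
                for sstate in range(4):
                    mask = parent == sstate
                    if mask.any():
                        child[mask] = np.searchsorted(cum[sstate], u[mask], side="right")
            if switch_rate > 0 and rng.random() < switch_rate:
                # template-switch move: flip one arm position symmetrically,
                # then homogenise the right arm from the left arm
                i = int(rng.integers(0, arm))
                cur = int(child[lo + i])
                child[lo + i] = int(rng.choice([b for b in range(4) if b != cur]))
                larm = child[lo : lo + arm]
                child[hi - arm : hi] = (3 - larm)[::-1]
                n_moves += 1
            states[node] = child
        leaves = {node.taxon.label: decode(states[node])
                  for node in t.leaf_node_iter()}
        msas[gene] = leaves
        cds[gene] = leaves[focal]
        truth_rows.append(dict(gene=gene, locus_start=lo + 1, locus_end=hi,
                               arm_len=arm, spacer_len=sp, n_switch_moves=n_moves))
    truth = pd.DataFrame(truth_rows)
    return PhyloDataset(tree=newick, msas=msas, cds=cds, truth=truth,
                        focal_taxon=focal)
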