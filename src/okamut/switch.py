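"""Fold-back template-switch models: fitting, simulation, and summaries.

The mechanism: replication stalls, the nascent strand folds back at an
inverted repeat (the hairpin stem), synthesis transiently copies the
nascent strand itself (a reverse-complement copy of upstream sequence),
and the fork then realigns to the true template. Four outcomes are
modelled:

* ``correction`` — a quasi-palindrome is homogenised into a perfect IR
  (one arm is rewritten from the reverse complement of the other);
* ``expansion`` — the palindrome grows by the self-copied stretch, with
  synthesis resuming exactly where it stalled;
* ``expansion_amplified`` — the fork realigns *behind* the stall, so a
  reference segment is duplicated in addition to the palindrome growth;
* ``expansion_resected`` — an exonuclease first removes nascent bases,
  which are never re-synthesised, before the fold-back.

All coordinates are 1-based on the top strand of the reference window.
Fitting is exact: a model is accepted only if simulating it reproduces
the observed alternate sequence nucleotide for nucleotide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from ._seq import revcomp
from .errors import OkamutError, WindowExceededError
from .repeats import InvertedRepeat, _quasi_scan, find_inverted_repeats

MODEL_TYPES = ("correction", "expansion", "expansion_amplified", "expansion_resected")


@dataclass(frozen=True)
class SwitchFitParams:
    min_arm: int = 5           # minimum stem arm for a fold-back
    max_spacer: int = 70       # maximum loop for IR detection
    min_loop: int = 3          # physical hairpin constraint for fold-back
    max_arm_edits: int = 3     # arm-edit budget for correction candidates
    max_resect: int = 50       # nt removable by exonuclease before fold-back
    max_self: int = 300        # nt copyable from the nascent strand
    max_window: int = 600      # short-event scope
    max_arm_len: int = 40      # cap on quasi-palindrome arm search


@dataclass(frozen=True)
class SwitchModel:
    """A fitted fold-back reconstruction.

    ``stall`` is the last top-strand position synthesised before any
    resection; ``fold_ir`` the stem used for fold-back; ``self_len`` the
    number of nt copied from the nascent strand; ``realign`` where
    synthesis resumes on the true template. Length bookkeeping is exact:
    len(alt) - len(ref) = expansion_len + amplification_len - resected_len.
    """

    model_type: str
    fold_ir: InvertedRepeat
    stall: int = 0
    self_len: int = 0
    realign: int = 0
    resected_len: int = 0
    expansion_len: int = 0
    amplification_len: int = 0
    homogenized_edits: int = 0
    correct_right: bool = True   # correction orientation
    strand: str = "+"
    notes: str = ""

    @property
    def fold_center(self) -> float:
        """Midpoint of the hairpin loop, top-strand coordinates."""
        return (self.fold_ir.left_end + self.fold_ir.right_start) / 2

    @property
    def length_change(self) -> int:
        return self.expansion_len + self.amplification_len - self.resected_len

    @property
    def n_switches(self) -> int:
        return 1 if self.model_type == "correction" else 2


def make_correction_model(ir: InvertedRepeat, correct_right: bool,
                          strand: str = "+", notes: str = "") -> SwitchModel:
    """Correction model; arm-length differences (indel edits) are booked
    as palindrome growth (expansion) or shrinkage (resection)."""
    src_len = (ir.left_end - ir.left_start + 1 if correct_right
               else ir.right_end - ir.right_start + 1)
    dst_len = (ir.right_end - ir.right_start + 1 if correct_right
               else ir.left_end - ir.left_start + 1)
    delta = src_len - dst_len
    return SwitchModel(
        model_type="correction",
        fold_ir=ir,
        homogenized_edits=ir.arm_edits,
        expansion_len=max(delta, 0),
        resected_len=max(-delta, 0),
        correct_right=correct_right,
        strand=strand,
        notes=notes,
    )


def make_expansion_model(ir: InvertedRepeat, self_len: int, realign: int,
                         resected_len: int = 0, strand: str = "+",
                         notes: str = "") -> SwitchModel:
    e = ir.right_end  # effective 3' end at fold-back
    stall = e + resected_len
    if resected_len > 0:
        if realign != stall + 1:
            raise OkamutError(
                "resected models resume at the original stall point")
        mtype = "expansion_resected"
        amp = 0
    elif realign == e + 1:
        mtype = "expansion"
        amp = 0
    elif realign <= e:
        mtype = "expansion_amplified"
        amp = e - realign + 1
    else:
        raise OkamutError("realign beyond stall requires resection")
    if self_len < 1:
        raise OkamutError("self_len must be >= 1 for expansion models")
    return SwitchModel(
        model_type=mtype,
        fold_ir=ir,
        stall=stall,
        self_len=self_len,
        realign=realign,
        resected_len=resected_len,
        expansion_len=self_len,
        amplification_len=amp,
        strand=strand,
        notes=notes,
    )


def _mirror_ir(ir: InvertedRepeat, n: int) -> InvertedRepeat:
    return InvertedRepeat(
        left_start=n - ir.right_end + 1,
        left_end=n - ir.right_start + 1,
        right_start=n - ir.left_end + 1,
        right_end=n - ir.left_start + 1,
        arm_len=ir.right_end - ir.right_start + 1,
        spacer_len=ir.spacer_len,
        arm_edits=ir.arm_edits,
    )


def _mirror_model(m: SwitchModel, n: int) -> SwitchModel:
    """Map a model between top-strand and bottom-strand frames."""
    return SwitchModel(
        model_type=m.model_type,
        fold_ir=_mirror_ir(m.fold_ir, n),
        stall=n - m.stall + 1 if m.stall else 0,
        self_len=m.self_len,
        realign=n - m.realign + 1 if m.realign else 0,
        resected_len=m.resected_len,
        expansion_len=m.expansion_len,
        amplification_len=m.amplification_len,
        homogenized_edits=m.homogenized_edits,
        correct_right=not m.correct_right,
        strand="-" if m.strand == "+" else "+",
        notes=m.notes,
    )


def _simulate_plus(ref: str, m: SwitchModel) -> str:
    ir = m.fold_ir
    if m.model_type == "correction":
        left = ref[ir.left_start - 1 : ir.left_end]
        right = ref[ir.right_start - 1 : ir.right_end]
        if m.correct_right:
            return ref[: ir.right_start - 1] + revcomp(left) + ref[ir.right_end :]
        return ref[: ir.left_start - 1] + revcomp(right) + ref[ir.left_end :]
    e = ir.right_end
    q0 = ir.left_start - 1  # 0-based
    if m.stall != e + m.resected_len:
        raise OkamutError("stall inconsistent with fold IR and resection")
    if q0 - m.self_len < 0 or m.realign < 1 or m.realign > len(ref) + 1:
        raise OkamutError("model coordinates fall outside the reference window")
    appended = revcomp(ref[q0 - m.self_len : q0])
    return ref[:e] + appended + ref[m.realign - 1 :]


def simulate_switch(ref_seq: str, model: SwitchModel) -> str:
    """Deterministically produce the mutated strand implied by a model.

    Raises :class:`OkamutError` if the model is inconsistent with the
    reference window. The exact length identity
    len(alt) - len(ref) = expansion + amplification - resection
    holds for every simulated model.
    """
    if model.model_type not in MODEL_TYPES:
        raise OkamutError(f"unknown model type {model.model_type!r}")
    if model.strand == "+":
        alt = _simulate_plus(ref_seq, model)
    else:
        m2 = _mirror_model(model, len(ref_seq))
        alt = revcomp(_simulate_plus(revcomp(ref_seq), m2))
    if len(alt) - len(ref_seq) != model.length_change:
        raise OkamutError("length bookkeeping violated by model")
    return alt


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _common_prefix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def _common_suffix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[-1 - i] == b[-1 - i]:
        i += 1
    return i


def _parsimony_key(m: SwitchModel):
    # fewest switches, smallest self-copy, smallest resection,
    # leftmost fold centre; top strand preferred on full ties
    return (m.n_switches, m.self_len, m.resected_len, m.fold_ir.left_start,
            0 if m.strand == "+" else 1)


def _fit_one_strand(ref: str, alt: str, params: SwitchFitParams,
                    strand: str) -> list[SwitchModel]:
    n = len(ref)
    cp = _common_prefix(ref, alt)
    cs = _common_suffix(ref, alt)
    cands: list[SwitchModel] = []

    diff_lo = cp  # 0-based first differing ref position (approximate)
    diff_hi = max(diff_lo, n - cs - 1)

    # --- correction candidates (only near-length-preserving changes) ---
    if abs(len(alt) - len(ref)) <= params.max_arm_edits:
        reach = params.max_arm_len + params.max_spacer + params.max_arm_len
        w0 = max(0, diff_lo - reach)
        w1 = min(n, diff_hi + 1 + reach)
        sub = ref[w0:w1]
        # full Pareto candidate set; exact-match simulation is the filter
        for qir in _quasi_scan(
            sub,
            min_arm=params.min_arm,
            max_spacer=params.max_spacer,
            max_arm_edits=params.max_arm_edits,
            max_arm_len=params.max_arm_len,
            focus=(diff_lo - w0, diff_hi - w0),
        ):
            gir = InvertedRepeat(
                left_start=qir.left_start + w0,
                left_end=qir.left_end + w0,
                right_start=qir.right_start + w0,
                right_end=qir.right_end + w0,
                arm_len=qir.arm_len,
                spacer_len=qir.spacer_len,
                arm_edits=qir.arm_edits,
            )
            for correct_right in (True, False):
                m = make_correction_model(gir, correct_right, strand="+")
                if _simulate_plus(ref, m) == alt:
                    cands.append(m)

    # --- expansion-family candidates ---
    for ir in find_inverted_repeats(
        ref, min_arm=params.min_arm, max_spacer=params.max_spacer,
        min_loop=params.min_loop,
    ):
        e = ir.right_end
        if e > cp:
            continue  # ref prefix through the stem must be conserved
        q0 = ir.left_start - 1
        # maximal self-copy run: alt continues with revcomp of the
        # sequence upstream of the left arm
        sl_max = 0
        while (
            sl_max < params.max_self
            and q0 - sl_max - 1 >= 0
            and e + sl_max < len(alt)
            and alt[e + sl_max] == revcomp(ref[q0 - sl_max - 1])
        ):
            sl_max += 1
        for sl in range(1, sl_max + 1):
            rem = len(alt) - e - sl
            if rem < 0 or rem > n:
                continue
            if rem > 0 and rem > cs:
                continue  # alt tail must equal ref tail
            r = n - rem + 1
            if r <= e:
                m = make_expansion_model(ir, sl, r, 0, strand="+")
            elif r == e + 1:
                m = make_expansion_model(ir, sl, r, 0, strand="+")
            else:
                res = r - e - 1
                if res > params.max_resect:
                    continue
                m = make_expansion_model(ir, sl, r, res, strand="+")
            cands.append(m)

    if strand == "-":
        cands = [_mirror_model(m, n) for m in cands]
    return cands


def fit_switch_model(
    ref_seq: str, alt_seq: str, params: Optional[SwitchFitParams] = None
) -> Optional[SwitchModel]:
    """Most parsimonious fold-back model that exactly explains alt from ref.

    Candidates are enumerated from the IRs and quasi-palindromes of the
    reference window on both strands, forward-simulated, and kept only on
    an exact sequence match. Ties are broken by fewest template switches,
    then smallest self-copy length, then smallest resection, then
    leftmost fold centre (top-strand coordinates are always reported).
    Returns None when no candidate reproduces the alternate sequence.
    """
    params = params or SwitchFitParams()
    if ref_seq == alt_seq:
        raise ValueError("ref_seq and alt_seq must differ")
    if len(ref_seq) > params.max_window or len(alt_seq) > params.max_window:
        raise WindowExceededError(
            f"window exceeds {params.max_window} nt short-event scope")
    cands = _fit_one_strand(ref_seq, alt_seq, params, "+")
    rr, ra = revcomp(ref_seq), revcomp(alt_seq)
    cands += _fit_one_strand(rr, ra, params, "-")
    good = [m for m in cands if simulate_switch(ref_seq, m) == alt_seq]
    if not good:
        return None
    good.sort(key=_parsimony_key)
    best = good[0]
    # flag mechanistically equivalent alternatives
    alts = sum(1 for m in good[1:] if _parsimony_key(m)[:1] == _parsimony_key(best)[:1])
    if alts:
        best = SwitchModel(
            **{**best.__dict__, "notes": (best.notes + " " if best.notes else "")
               + f"{alts} equivalent-output model(s) exist"})
    return best


def annotate_switch_outcomes(models: Sequence[SwitchModel]) -> pd.DataFrame:
    """Tabulate fitted models by type and expansion/amplification dominance."""
    rows = []
    for m in models:
        if m.model_type == "correction":
            dom = "correction"
        elif m.expansion_len > m.amplification_len:
            dom = "expansion-dominant"
        elif m.amplification_len > m.expansion_len:
            dom = "amplification-dominant"
        else:
            dom = "balanced"
        rows.append(
            {
                "model_type": m.model_type,
                "dominance": dom,
                "expansion_len": m.expansion_len,
                "amplification_len": m.amplification_len,
                "resected_len": m.resected_len,
                "homogenized_edits": m.homogenized_edits,
                "length_change": m.length_change,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "model_type", "dominance", "expansion_len", "amplification_len",
            "resected_len", "homogenized_edits", "length_change",
        ],
    )
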