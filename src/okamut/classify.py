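"""Mechanistic classification of locus-level events.

Each filtered event is assigned to exactly one mechanism class by a
deterministic cascade:

1. ``ssr`` — the INDEL is a whole-number change of units inside a simple
   sequence repeat (micro-satellite scale, period <= 6 by default);
2. ``direct_repeat`` — the INDEL decomposes as ABA <-> ABABA, a
   duplication/deletion mediated by a short direct repeat A flanking a
   unique spacer B;
3. ``palindrome_expansion`` / ``quasi_palindrome_correction`` — a
   fold-back template-switch model reproduces the alternate sequence
   exactly;
4. ``other`` — the only fallback.

When both an SSR tract and a direct-repeat decomposition fit, perfect
evidence wins: a pure tract keeps the event in ``ssr``; an event in a
non-perfect simple-repeat region whose direct-repeat copies fit is
classified ``direct_repeat``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .errors import WindowExceededError
from .events import Event, mutation_rate
from .repeats import (
    TandemRepeat,
    decompose_direct_repeat,
    find_tandem_repeats,
)
from .switch import SwitchFitParams, SwitchModel, fit_switch_model

MECH_CLASSES = (
    "ssr",
    "direct_repeat",
    "palindrome_expansion",
    "quasi_palindrome_correction",
    "other",
)


@dataclass(frozen=True)
class ClassifyParams:
    ssr_max_period: int = 6
    ssr_min_purity: float = 0.9
    ssr_window: int = 60          # reference context scanned around the event
    dr_min_similarity: float = 0.9
    switch: SwitchFitParams = field(default_factory=SwitchFitParams)
    switch_flank: int = 250       # flank used to build ref/alt fit windows


@dataclass(frozen=True)
class Classification:
    mech_class: str
    direction: str                # insertion | deletion | unknown_mixed
    evidence: object = None       # TandemRepeat / DirectRepeatDecomposition / SwitchModel
    notes: str = ""

    def __post_init__(self):
        if self.mech_class not in MECH_CLASSES:
            raise ValueError(f"unknown mech_class {self.mech_class!r}")


def _direction(event: Event) -> str:
    d = event.length_change
    if d > 0:
        return "insertion"
    if d < 0:
        return "deletion"
    return "unknown_mixed"


def _is_rotation(a: str, b: str) -> bool:
    return len(a) == len(b) and a in b + b


def _exact_tract(
    s: str, site_lo: int, site_hi: int, unit: str, is_insertion: bool,
    max_period: int,
) -> Optional[TandemRepeat]:
    """Perfect tandem tract through the event site, smallest period first."""
    L = len(unit)
    for p in range(1, min(L, max_period) + 1):
        if L % p != 0:
            continue
        # the allele itself must be p-periodic (whole units of the tract)
        if unit != unit[:p] * (L // p):
            continue
        lo = site_lo
        while lo - 1 >= 0 and lo - 1 + p < len(s) and s[lo - 1] == s[lo - 1 + p]:
            lo -= 1
        hi = site_hi
        while hi + p < len(s) and s[hi] == s[hi + p]:
            hi += 1
        span = hi + p - lo
        if is_insertion:
            if span < 2 * p:
                continue
            # inserted blocks must continue the tract in phase
            if not (s[site_lo : site_lo + L] == unit or s[site_lo - L : site_lo] == unit):
                continue
        else:
            if span < L + p:
                continue
        return TandemRepeat(
            unit=s[lo : lo + p], period=p, copy_number=span / p,
            start=lo + 1, end=hi + p, purity=1.0,
        )
    return None


def _ssr_evidence(event: Event, params: ClassifyParams) -> Optional[TandemRepeat]:
    """A tandem tract explaining the INDEL as whole-unit slippage.

    The tract must span the event locus on the reference side, the length
    change must be a whole number of periods, and the inserted sequence
    (if any) must be built from rotations of the tract unit. A perfect
    tract through the site is sought first; impure tracts come from the
    purity-scored tandem scanner.
    """
    unit = event.alt_allele if event.length_change > 0 else event.ref_allele
    if not unit:
        return None
    w = params.ssr_window
    left = event.flank_left[-w:]
    right = event.flank_right[:w]
    ref_local = left + event.ref_allele + right
    site_lo = len(left)  # 0-based start of the event inside ref_local
    site_hi = site_lo + len(event.ref_allele)
    exact = _exact_tract(
        ref_local, site_lo, site_hi, unit,
        event.length_change > 0, params.ssr_max_period,
    )
    if exact is not None:
        return exact
    best = None
    for tr in find_tandem_repeats(
        ref_local,
        max_period=params.ssr_max_period,
        min_purity=params.ssr_min_purity,
    ):
        if len(unit) % tr.period != 0:
            continue
        # tract must reach the event site
        if tr.end < site_lo or tr.start > site_hi + 1:
            continue
        # every unit-sized block of the allele must be a rotation of the
        # tract unit (allowing register shifts)
        blocks = [unit[i : i + tr.period] for i in range(0, len(unit), tr.period)]
        if not all(_is_rotation(b, tr.unit) for b in blocks):
            continue
        if best is None or (tr.purity, tr.end - tr.start) > (
            best.purity, best.end - best.start
        ):
            best = tr
    return best


def classify_event(event: Event, params: Optional[ClassifyParams] = None) -> Classification:
    """Assign one mechanism class to a filtered event with flanks attached."""
    params = params or ClassifyParams()
    if not event.flank_left and not event.flank_right:
        raise ValueError("classify_event requires flanks attached to the event")
    direction = _direction(event)

    if event.event_type == "snp":
        # an isolated substitution is indistinguishable from a point
        # mutation; only clustered changes are tested for fold-back
        return Classification("other", direction)

    if event.event_type in ("snp_cluster", "mixed"):
        model = _fit_switch(event, params)
        if model is not None and model.model_type == "correction":
            return Classification("quasi_palindrome_correction", direction, model)
        if model is not None:
            return Classification("palindrome_expansion", direction, model)
        return Classification("other", direction)

    # pure INDELs
    ssr = _ssr_evidence(event, params)
    dr = decompose_direct_repeat(event, min_similarity=params.dr_min_similarity)
    if ssr is not None and ssr.purity >= 1.0:
        return Classification("ssr", direction, ssr)
    if dr is not None:
        note = "imperfect simple-repeat context also fits" if ssr is not None else ""
        return Classification("direct_repeat", direction, dr, notes=note)
    if ssr is not None:
        return Classification("ssr", direction, ssr)

    model = _fit_switch(event, params)
    if model is not None:
        if model.model_type == "correction":
            return Classification("quasi_palindrome_correction", direction, model)
        return Classification("palindrome_expansion", direction, model)
    return Classification("other", direction)


def _fit_switch(event: Event, params: ClassifyParams) -> Optional[SwitchModel]:
    f = params.switch_flank
    left = event.flank_left[-f:]
    right = event.flank_right[:f]
    ref_win = left + event.ref_allele + right
    alt_win = left + event.alt_allele + right
    if ref_win == alt_win:
        return None
    try:
        return fit_switch_model(ref_win, alt_win, params.switch)
    except WindowExceededError:
        return None


def classify_all(
    events: Sequence[Event],
    params: Optional[ClassifyParams] = None,
    n_colonies: Optional[int] = None,
    n_generations: Optional[int] = None,
    assayable_bp: Optional[int] = None,
) -> tuple[pd.DataFrame, dict]:
    """Classify a cohort; returns (per-event table, summary).

    The summary carries per-class counts, insertion/deletion counts per
    class, and — when the cohort denominators are supplied — per-class
    mutation rates (events per colony per generation per base pair).
    """
    params = params or ClassifyParams()
    rows = []
    for ev in events:
        c = classify_event(ev, params)
        rows.append(
            {
                "chrom": ev.chrom,
                "pos": ev.pos,
                "ref_allele": ev.ref_allele,
                "alt_allele": ev.alt_allele,
                "event_type": ev.event_type,
                "strains": ";".join(sorted(ev.strains_with_alt)),
                "mech_class": c.mech_class,
                "direction": c.direction,
                "evidence": type(c.evidence).__name__ if c.evidence is not None else "",
                "notes": c.notes,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref_allele", "alt_allele", "event_type",
            "strains", "mech_class", "direction", "evidence", "notes",
        ],
    )
    summary: dict = {"n_events": len(rows), "per_class": {}, "per_direction": {}}
    for mc in MECH_CLASSES:
        sub = table[table.mech_class == mc] if len(table) else table
        n = int(len(sub))
        entry = {
            "count": n,
            "insertions": int((sub.direction == "insertion").sum()) if n else 0,
            "deletions": int((sub.direction == "deletion").sum()) if n else 0,
        }
        if None not in (n_colonies, n_generations, assayable_bp):
            entry["rate"] = mutation_rate(
                n, n_colonies, n_generations, assayable_bp
            ).rate
        summary["per_class"][mc] = entry
    if len(table):
        summary["per_direction"] = table.groupby("direction").size().to_dict()
        summary["insertion_deletion_ratio"] = (
            float(summary["per_direction"].get("insertion", 0))
            / summary["per_direction"].get("deletion", 1)
            if summary["per_direction"].get("deletion", 0)
            else float("inf")
            if summary["per_direction"].get("insertion", 0)
            else 0.0
        )
    return table, summary
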