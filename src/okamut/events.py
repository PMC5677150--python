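"""Locus-level event extraction from multi-strain alignments, filtering,
recurrent-locus grouping, and mutation-rate estimation.

Coordinates: events use 1-based inclusive positions on the reference
(``pos`` is the first affected reference base; a pure insertion with an
empty ``ref_allele`` is anchored left, i.e. the alternate chromosome is
``ref[:pos-1] + alt_allele + ref[pos-1:]``). Mask intervals follow BED
semantics (0-based, half-open). INDELs are normalised by maximal left
shift so that a locus has one deterministic identity for grouping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import ConfigurationError, MalformedAlignmentError

EVENT_TYPES = ("insertion", "deletion", "snp", "snp_cluster", "mixed")


@dataclass(frozen=True)
class StrainSet:
    """A group of sequenced colonies from one line at one subculture depth."""

    line_id: str
    subculture: int
    strain_ids: tuple[str, ...]

    def __post_init__(self):
        if self.subculture < 0:
            raise ValueError("subculture must be >= 0")
        if len(set(self.strain_ids)) != len(self.strain_ids):
            raise ValueError("strain_ids must be unique")


@dataclass(frozen=True)
class Event:
    """One locus-level change (INDEL, SNP, SNP cluster or mixed run)."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    strains_with_alt: frozenset
    event_type: str
    flank_left: str = ""
    flank_right: str = ""
    support: Optional[Mapping[str, float]] = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref_allele must differ from alt_allele")
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event_type {self.event_type!r}")

    @property
    def length_change(self) -> int:
        return len(self.alt_allele) - len(self.ref_allele)

    @property
    def ref_span(self) -> tuple[int, int]:
        """1-based inclusive span of affected reference bases.

        A pure insertion affects the two bases flanking the insertion
        point; the span is clamped to start at ``pos`` minus one.
        """
        if self.ref_allele:
            return (self.pos, self.pos + len(self.ref_allele) - 1)
        return (max(1, self.pos - 1), self.pos)

    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


@dataclass
class LocusGroup:
    chrom: str
    events: list
    recurrent: bool

    @property
    def start(self) -> int:
        return min(e.pos for e in self.events)

    @property
    def end(self) -> int:
        return max(e.ref_span[1] for e in self.events)


@dataclass(frozen=True)
class MutationRate:
    n_events: int
    n_colonies: int
    n_generations: int
    assayable_bp: int
    rate: float


# ---------------------------------------------------------------------------
# left alignment
# ---------------------------------------------------------------------------


def left_align_indel(ref_seq: str, pos: int, ref_allele: str, alt_allele: str):
    """Shift a pure INDEL maximally left on the reference (VCF practice).

    Returns (pos, ref_allele, alt_allele). Non-indel events are returned
    unchanged.
    """
    if ref_allele and alt_allele:
        return pos, ref_allele, alt_allele
    unit = ref_allele or alt_allele
    if not unit:
        return pos, ref_allele, alt_allele
    while pos > 1 and unit[-1] == ref_seq[pos - 2]:
        unit = ref_seq[pos - 2] + unit[:-1]
        pos -= 1
    if ref_allele:
        return pos, unit, ""
    return pos, "", unit


def apply_event(ref_seq: str, event: Event) -> str:
    """Apply one event's alternate allele to a reference chromosome string."""
    i = event.pos - 1
    return ref_seq[:i] + event.alt_allele + ref_seq[i + len(event.ref_allele):]


def apply_events(ref_seq: str, events: Sequence[Event]) -> str:
    """Apply non-overlapping events (any order) to a reference string."""
    out = ref_seq
    for ev in sorted(events, key=lambda e: e.pos, reverse=True):
        out = apply_event(out, ev)
    return out


# ---------------------------------------------------------------------------
# extraction from a multiple sequence alignment
# ---------------------------------------------------------------------------


def _row_events(ref_row: str, row: str, ref_seq: str, chrom: str,
                cluster_window: int):
    """Raw (pos, ref_allele, alt_allele, event_type) for one strain row."""
    ncol = len(ref_row)
    diffs = [i for i in range(ncol)
             if row[i] != ref_row[i] and not (row[i] == "-" and ref_row[i] == "-")]
    if not diffs:
        return []
    # ref base count up to and including each column
    ref_count = []
    c = 0
    for ch in ref_row:
        if ch != "-":
            c += 1
        ref_count.append(c)
    # maximal runs of disagreeing columns
    runs = []
    start = prev = diffs[0]
    for i in diffs[1:]:
        if i == prev + 1:
            prev = i
        else:
            runs.append((start, prev))
            start = prev = i
    runs.append((start, prev))
    # merge runs whose reference-coordinate gap is within the cluster window
    merged = [list(runs[0])]
    for c0, c1 in runs[1:]:
        prev_end_pos = ref_count[merged[-1][1]]
        next_start_pos = ref_count[c0 - 1] + 1 if c0 > 0 else 1
        if next_start_pos - prev_end_pos <= cluster_window:
            merged[-1][1] = c1
        else:
            merged.append([c0, c1])
    out = []
    for c0, c1 in merged:
        ref_allele = ref_row[c0 : c1 + 1].replace("-", "")
        alt_allele = row[c0 : c1 + 1].replace("-", "")
        if ref_allele == alt_allele:
            continue
        pos = (ref_count[c0 - 1] if c0 > 0 else 0) + 1
        has_ref_gap = "-" in ref_row[c0 : c1 + 1]
        has_row_gap = "-" in row[c0 : c1 + 1]
        if not ref_allele:
            etype = "insertion"
        elif not alt_allele:
            etype = "deletion"
        elif not has_ref_gap and not has_row_gap:
            etype = "snp" if len(ref_allele) == 1 else "snp_cluster"
        else:
            etype = "mixed"
        if etype in ("insertion", "deletion"):
            pos, ref_allele, alt_allele = left_align_indel(
                ref_seq, pos, ref_allele, alt_allele)
        out.append((pos, ref_allele, alt_allele, etype))
    return out


def extract_events_from_msa(
    msa: Mapping[str, str],
    ref_id: str,
    focal: StrainSet | Sequence[StrainSet],
    controls: StrainSet | Sequence[StrainSet] | None = None,
    chrom: str = "chr",
    cluster_window: int = 25,
    flank: int = 300,
    drop_shared_all_focal: bool = True,
) -> list[Event]:
    """Extract locus-level events for focal strains from a per-chromosome MSA.

    Events present in every focal strain are dropped (changes fixed in
    the whole cohort are uninformative about ongoing mutation), as are
    events also carried by any control strain (shared ancestry rather
    than new mutation).
    """
    focal_sets = [focal] if isinstance(focal, StrainSet) else list(focal)
    control_sets = ([] if controls is None
                    else [controls] if isinstance(controls, StrainSet)
                    else list(controls))
    focal_ids = [s for fs in focal_sets for s in fs.strain_ids]
    control_ids = [s for cs in control_sets for s in cs.strain_ids]
    if ref_id not in msa:
        raise ConfigurationError(f"reference row {ref_id!r} missing from MSA")
    lengths = {len(v) for v in msa.values()}
    if len(lengths) != 1:
        raise MalformedAlignmentError("MSA rows have unequal lengths")
    for sid in focal_ids + control_ids:
        if sid not in msa:
            raise ConfigurationError(f"strain row {sid!r} missing from MSA")

    ref_row = msa[ref_id].upper()
    ref_seq = ref_row.replace("-", "")

    per_key: dict[tuple, dict] = {}
    for sid in focal_ids:
        for pos, ra, aa, etype in _row_events(
            ref_row, msa[sid].upper(), ref_seq, chrom, cluster_window
        ):
            rec = per_key.setdefault((pos, ra, aa), {"etype": etype, "strains": set()})
            rec["strains"].add(sid)
    control_keys = set()
    for sid in control_ids:
        for pos, ra, aa, _ in _row_events(
            ref_row, msa[sid].upper(), ref_seq, chrom, cluster_window
        ):
            control_keys.add((pos, ra, aa))

    events = []
    for (pos, ra, aa), rec in sorted(per_key.items()):
        if drop_shared_all_focal and rec["strains"] >= set(focal_ids):
            continue
        if (pos, ra, aa) in control_keys:
            continue
        i = pos - 1
        fl = ref_seq[max(0, i - flank) : i]
        fr = ref_seq[i + len(ra) : i + len(ra) + flank]
        events.append(
            Event(
                chrom=chrom,
                pos=pos,
                ref_allele=ra,
                alt_allele=aa,
                strains_with_alt=frozenset(rec["strains"]),
                event_type=rec["etype"],
                flank_left=fl,
                flank_right=fr,
            )
        )
    return events


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def filter_events(
    events: Sequence[Event],
    ref: Mapping[str, str] | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
    exclude_telomeric_bp: int = 20_000,
    mask_intervals: Iterable[tuple[str, int, int]] | None = None,
    min_support_fraction: float = 0.9,
) -> list[Event]:
    """Drop events in telomere-proximal zones, over Ns, in masked
    intervals, or with weak per-strain support.

    ``mask_intervals`` are (chrom, start, end) in BED semantics. The
    support filter applies only to events that carry support fractions.
    Order is preserved and the operation is idempotent.
    """
    if chrom_lengths is None and ref is not None:
        chrom_lengths = {c: len(s) for c, s in ref.items()}
    masks: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in mask_intervals or []:
        masks.setdefault(c, []).append((s, e))
    out = []
    for ev in events:
        s1, e1 = ev.ref_span
        if chrom_lengths is not None and ev.chrom in chrom_lengths:
            n = chrom_lengths[ev.chrom]
            if s1 <= exclude_telomeric_bp or e1 > n - exclude_telomeric_bp:
                continue
        if ref is not None and ev.chrom in ref:
            if "N" in ref[ev.chrom][s1 - 1 : e1].upper():
                continue
        if any(s0 < e1 and s1 - 1 < e0 for s0, e0 in masks.get(ev.chrom, [])):
            continue
        if ev.support:
            if min(ev.support.values()) < min_support_fraction:
                continue
        out.append(ev)
    return out


# ---------------------------------------------------------------------------
# recurrent loci and rates
# ---------------------------------------------------------------------------


def group_recurrent_loci(events: Sequence[Event], window_bp: int = 25) -> list[LocusGroup]:
    """Partition events into locus groups by proximity chaining.

    Events on the same chromosome within ``window_bp`` of each other join
    one group. A group is recurrent when some alternate allele is carried
    by at least two strains, or at least two distinct alternate alleles
    occur at the locus.
    """
    groups: list[LocusGroup] = []
    cur: list[Event] = []
    for ev in sorted(events, key=lambda e: (e.chrom, e.pos)):
        if cur and ev.chrom == cur[-1].chrom and ev.pos - cur[-1].pos <= window_bp:
            cur.append(ev)
        else:
            if cur:
                groups.append(_make_group(cur))
            cur = [ev]
    if cur:
        groups.append(_make_group(cur))
    return groups


def _make_group(members: list[Event]) -> LocusGroup:
    multi_strain = any(len(e.strains_with_alt) >= 2 for e in members)
    distinct_alts = len({(e.pos, e.ref_allele, e.alt_allele) for e in members})
    return LocusGroup(
        chrom=members[0].chrom,
        events=list(members),
        recurrent=multi_strain or distinct_alts >= 2,
    )


def mutation_rate(
    events, n_colonies: int, n_generations: int, assayable_bp: int
) -> MutationRate:
    """Events per colony per generation per assayable base pair."""
    n = events if isinstance(events, int) else len(list(events))
    if n < 0:
        raise ValueError("event count must be non-negative")
    denom = n_colonies * n_generations * assayable_bp
    if denom <= 0:
        raise ValueError("colonies, generations and assayable bp must be positive")
    return MutationRate(
        n_events=n,
        n_colonies=n_colonies,
        n_generations=n_generations,
        assayable_bp=assayable_bp,
        rate=n / denom,
    )


# ---------------------------------------------------------------------------
# tabular IO and supplementary-table ingestion
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ["chrom", "pos", "ref_allele", "alt_allele", "event_type", "strains"]


def events_to_dataframe(events: Sequence[Event]) -> pd.DataFrame:
    rows = [
        {
            "chrom": e.chrom,
            "pos": e.pos,
            "ref_allele": e.ref_allele,
            "alt_allele": e.alt_allele,
            "event_type": e.event_type,
            "strains": ";".join(sorted(e.strains_with_alt)),
        }
        for e in events
    ]
    return pd.DataFrame(rows, columns=_TSV_COLUMNS)


def dataframe_to_events(
    df: pd.DataFrame, ref: Mapping[str, str] | None = None, flank: int = 300
) -> list[Event]:
    out = []
    for _, r in df.iterrows():
        ra = "" if pd.isna(r["ref_allele"]) else str(r["ref_allele"]).replace(".", "")
        aa = "" if pd.isna(r["alt_allele"]) else str(r["alt_allele"]).replace(".", "")
        fl = fr = ""
        pos = int(r["pos"])
        chrom = str(r["chrom"])
        if ref is not None and chrom in ref:
            seq = ref[chrom]
            i = pos - 1
            fl = seq[max(0, i - flank) : i]
            fr = seq[i + len(ra) : i + len(ra) + flank]
        strains = str(r.get("strains", "") or "")
        out.append(
            Event(
                chrom=chrom,
                pos=pos,
                ref_allele=ra,
                alt_allele=aa,
                strains_with_alt=frozenset(s for s in strains.split(";") if s),
                event_type=str(r["event_type"]),
                flank_left=fl,
                flank_right=fr,
            )
        )
    return out


def ingest_event_table(
    path, column_map: Mapping[str, str] | None = None
) -> tuple[pd.DataFrame, dict]:
    """Ingest a supplementary-style event list (TSV export).

    ``column_map`` maps the standard names (chrom, pos, ref_allele,
    alt_allele, event_type, strains, mech_class) to the file's column
    headers. Returns the normalised table and a tally dict reporting both
    the locus count and the strain-by-locus occurrence count (which
    differ when multiple strains share an event), plus per-class counts
    when a class column is present.
    """
    df = pd.read_csv(path, sep="\t")
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    tallies: dict = {}
    tallies["n_loci"] = int(df.drop_duplicates(subset=["chrom", "pos"]).shape[0])
    if "strains" in df.columns:
        occ = df["strains"].fillna("").astype(str).map(
            lambda s: max(1, len([x for x in s.split(";") if x]))
        )
        tallies["n_occurrences"] = int(occ.sum())
    else:
        tallies["n_occurrences"] = int(df.shape[0])
    if "mech_class" in df.columns:
        tallies["per_class"] = df.groupby("mech_class").size().to_dict()
    return df, tallies
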