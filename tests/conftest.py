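"""Shared fixtures: the default synthetic cohort is expensive (a ~1 Mb
toy genome, 14 strains, full extraction + classification), so it is
built once per session and reused by the classifier and acceptance
tests."""

from __future__ import annotations

import numpy as np
import pytest

from okamut.classify import classify_all
from okamut.events import extract_events_from_msa
from okamut.synth import GenomeDesign, MutationConfig, make_genome, mutate_strains

COHORT_GENOME_SEED = 101
COHORT_MUT_SEED = 202


@pytest.fixture(scope="session")
def default_cohort():
    ref, features = make_genome(GenomeDesign(seed=COHORT_GENOME_SEED))
    cohort = mutate_strains(ref, features, MutationConfig(seed=COHORT_MUT_SEED))
    return ref, features, cohort


@pytest.fixture(scope="session")
def cohort_events(default_cohort):
    _, _, cohort = default_cohort
    events = []
    for chrom, msa in cohort.msas.items():
        events.extend(
            extract_events_from_msa(
                msa, cohort.ref_id, cohort.focal, cohort.controls, chrom=chrom
            )
        )
    return events


@pytest.fixture(scope="session")
def cohort_classified(cohort_events):
    return classify_all(cohort_events)


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def plant_palindrome(rng, arm=12, spacer=5, left_ctx=110, right_ctx=110,
                     min_loop=3, unique=True):
    """Random window with one verified planted perfect palindrome."""
    from okamut._seq import revcomp
    from okamut.repeats import find_inverted_repeats

    for _ in range(60):
        a = random_seq(rng, arm)
        body = a + random_seq(rng, spacer) + revcomp(a)
        ref = random_seq(rng, left_ctx) + body + random_seq(rng, right_ctx)
        irs = find_inverted_repeats(ref, min_arm=5, max_spacer=70, min_loop=min_loop)
        mine = [r for r in irs if r.left_start == left_ctx + 1
                and r.arm_len == arm and r.spacer_len == spacer]
        if len(mine) != 1:
            continue
        rivals = [r for r in irs if r is not mine[0] and r.arm_len >= arm]
        if unique and rivals:
            continue
        return ref, mine[0]
    raise AssertionError("could not plant a clean palindrome")


def plant_quasi(rng, arm=12, spacer=5, edits=2, ctx=110):
    """Random window with one planted quasi-palindrome (mismatch edits)."""
    from okamut._seq import revcomp
    from okamut.repeats import find_quasi_palindromes

    for _ in range(60):
        a = random_seq(rng, arm)
        right = list(revcomp(a))
        for p in rng.choice(np.arange(1, arm - 1), size=edits, replace=False):
            cur = right[p]
            right[p] = str(rng.choice([b for b in "ACGT" if b != cur]))
        ref = (random_seq(rng, ctx) + a + random_seq(rng, spacer)
               + "".join(right) + random_seq(rng, ctx))
        qs = [q for q in find_quasi_palindromes(ref, 5, 70, max_arm_edits=3)
              if q.left_start == ctx + 1 and q.arm_edits == edits]
        if qs:
            return ref, qs[0]
    raise AssertionError("could not plant a clean quasi-palindrome")
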