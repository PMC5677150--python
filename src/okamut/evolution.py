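"""Cross-species inverted-repeat evolution: counting distinct perfect-IR
"forms" at orthologous loci and testing them against a substitution-only
simulation null.

A "form" is the exact perfect-IR sequence (left arm, spacer content,
right arm) observed in one genome at an orthologous locus. Multiple
distinct perfect forms at one locus across a phylogeny are the
evolutionary signature of quasi-palindrome-to-palindrome conversion by
template switching: point substitutions alone rarely carry a locus from
one perfect palindrome to a different perfect palindrome.

The null model evolves the locus root sequence down the given tree under
HKY85 (empirical base frequencies, transition/transversion ratio
estimated from the alignment, homogeneous site rates) with no
template-switching move, and the empirical p-value compares the observed
form count to the simulated distribution (one-sided, add-one corrected).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import expm

from ._seq import decode, encode
from .errors import ConfigurationError
from .repeats import find_inverted_repeats, find_quasi_palindromes


@dataclass
class OrthoLocus:
    """Aligned subsequences covering one IR locus across genomes.

    ``taxa`` maps taxon name to the aligned (possibly gapped) locus
    subsequence, or None where the region could not be identified.
    """

    locus_id: str
    gene_id: str
    taxa: Mapping[str, Optional[str]]
    columns: tuple[int, int] = (0, 0)  # 0-based half-open source MSA columns


@dataclass
class IRFormProfile:
    locus_id: str
    status: dict            # taxon -> "form-<k>" | "quasi" | "none" | "missing"
    forms: dict             # form key -> form index
    n_forms: int
    null_counts: Optional[np.ndarray] = None
    p_value: Optional[float] = None


@dataclass
class PhyloNullConfig:
    tree: "dendropy.Tree | str"
    kappa: Optional[float] = None     # transition/transversion rate ratio
    freqs: Optional[np.ndarray] = None
    n_reps: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


# ---------------------------------------------------------------------------
# form counting
# ---------------------------------------------------------------------------


def _best_ir(seq: str, min_arm: int, max_spacer: int):
    irs = find_inverted_repeats(seq, min_arm=min_arm, max_spacer=max_spacer)
    if not irs:
        return None
    return max(irs, key=lambda r: (r.arm_len, -r.left_start))


def _batch_form_keys(seqs: Sequence[str], min_arm: int, max_spacer: int) -> list:
    """Best perfect-IR form key per sequence, via one concatenated scan.

    Sequences are joined with N runs longer than ``max_spacer``; N never
    pairs, so no inverted repeat can bridge two segments.
    """
    if not seqs:
        return []
    sep = "N" * (max_spacer + 1)
    joined = sep.join(seqs)
    offsets = []
    pos = 0
    for s in seqs:
        offsets.append(pos)
        pos += len(s) + len(sep)
    starts = np.array(offsets)
    best: list = [None] * len(seqs)
    best_ir: list = [None] * len(seqs)
    for ir in find_inverted_repeats(joined, min_arm=min_arm, max_spacer=max_spacer):
        i = int(np.searchsorted(starts, ir.left_start - 1, side="right")) - 1
        cur = best_ir[i]
        if cur is None or (ir.arm_len, -(ir.left_start - starts[i])) > (
            cur.arm_len, -(cur.left_start - starts[i]),
        ):
            best_ir[i] = ir
    for i, ir in enumerate(best_ir):
        if ir is not None:
            off = int(starts[i])
            seq = seqs[i]
            best[i] = (
                seq[ir.left_start - 1 - off : ir.left_end - off],
                seq[ir.left_end - off : ir.right_start - 1 - off],
                seq[ir.right_start - 1 - off : ir.right_end - off],
            )
    return best


def count_ir_forms(
    locus: OrthoLocus,
    min_arm: int = 5,
    max_spacer: int = 70,
    classify_quasi: bool = True,
    quasi_max_edits: int = 3,
) -> IRFormProfile:
    """Bin taxa by their exact perfect-IR variant at an orthologous locus.

    Each taxon's subsequence is degapped and scanned; taxa with a perfect
    IR are binned by the exact (left arm, spacer, right arm) string
    triple; n_forms is the number of distinct bins. Taxa with only a
    quasi-palindrome are marked "quasi" (when ``classify_quasi``), taxa
    with no IR-like structure "none", absent/truncated regions "missing".
    """
    status: dict = {}
    forms: dict = {}
    for taxon, sub in locus.taxa.items():
        if sub is None:
            status[taxon] = "missing"
            continue
        seq = sub.replace("-", "").upper()
        if len(seq) < 2 * min_arm:
            status[taxon] = "missing"
            continue
        ir = _best_ir(seq, min_arm, max_spacer)
        if ir is not None:
            key = ir.arm_seqs(seq)
            if key not in forms:
                forms[key] = len(forms) + 1
            status[taxon] = f"form-{forms[key]}"
        elif classify_quasi and find_quasi_palindromes(
            seq, min_arm=min_arm, max_spacer=min(max_spacer, len(seq)),
            max_arm_edits=quasi_max_edits,
        ):
            status[taxon] = "quasi"
        else:
            status[taxon] = "none"
    return IRFormProfile(
        locus_id=locus.locus_id, status=status, forms=forms, n_forms=len(forms)
    )


# ---------------------------------------------------------------------------
# HKY85 machinery
# ---------------------------------------------------------------------------

_TRANSITION = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T


def hky_rate_matrix(kappa: float, freqs: np.ndarray) -> np.ndarray:
    """HKY85 instantaneous rate matrix, scaled to one expected
    substitution per unit branch length."""
    freqs = np.asarray(freqs, dtype=float)
    freqs = freqs / freqs.sum()
    Q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            Q[i, j] = freqs[j] * (kappa if (i, j) in _TRANSITION else 1.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(freqs * np.diag(Q)).sum()
    return Q / mu


def estimate_kappa(seqs: Sequence[str], pseudo: float = 1.0) -> float:
    """Crude transition/transversion rate-ratio estimate from pairwise
    differences in aligned sequences."""
    ts = tv = 0
    seqs = [s.upper() for s in seqs]
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            for a, b in zip(seqs[i], seqs[j]):
                if a == b or "-" in (a, b) or "N" in (a, b):
                    continue
                x, y = "ACGT".find(a), "ACGT".find(b)
                if x < 0 or y < 0:
                    continue
                if (x, y) in _TRANSITION:
                    ts += 1
                else:
                    tv += 1
    # rate ratio ~ 2 * (ts/tv count ratio) under equal frequencies
    return 2.0 * (ts + pseudo) / (tv + 2 * pseudo)


def base_frequencies(seqs: Sequence[str], pseudo: float = 1.0) -> np.ndarray:
    counts = np.full(4, pseudo)
    for s in seqs:
        codes = encode(s.replace("-", "").upper())
        for c in range(4):
            counts[c] += int((codes == c).sum())
    return counts / counts.sum()


class _Evolver:
    """Evolves integer-coded sequences down a dendropy tree under HKY."""

    def __init__(self, tree: dendropy.Tree, kappa: float, freqs: np.ndarray):
        self.tree = tree
        self.Q = hky_rate_matrix(kappa, freqs)
        self._pcache: dict[float, np.ndarray] = {}

    def _P(self, t: float) -> np.ndarray:
        if t not in self._pcache:
            P = expm(self.Q * t)
            # cumulative rows for categorical sampling
            self._pcache[t] = np.cumsum(P, axis=1)
        return self._pcache[t]

    def evolve(self, root_codes: np.ndarray, rng: np.random.Generator) -> dict:
        """One realisation; returns taxon label -> code array."""
        out = self.evolve_batch(root_codes, 1, rng)
        return {t: a[0] for t, a in out.items()}

    def evolve_batch(
        self, root_codes: np.ndarray, n_reps: int, rng: np.random.Generator
    ) -> dict:
        """``n_reps`` independent realisations in one traversal; returns
        taxon label -> (n_reps, L) code matrix."""
        states = {}
        leaves = {}
        root = np.broadcast_to(root_codes, (n_reps, root_codes.size))
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                states[node] = root
                continue
            parent = states[node.parent_node]
            t = node.edge.length or 0.0
            if t <= 0:
                child = parent
            else:
                cum = self._P(t)
                u = rng.random(parent.shape)
                child = np.empty(parent.shape, dtype=parent.dtype)
                for s in range(4):
                    mask = parent == s
                    if mask.any():
                        child[mask] = np.searchsorted(cum[s], u[mask], side="right")
            states[node] = child
            if node.is_leaf():
                leaves[node.taxon.label] = child
        return leaves


def _as_tree(tree) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    return dendropy.Tree.get(data=tree, schema="newick")


def majority_root(seqs: Sequence[str]) -> str:
    """Majority-rule column consensus (gaps ignored; ties by base order),
    used as the root state for the null simulation."""
    ncol = max(len(s) for s in seqs)
    out = []
    for i in range(ncol):
        counts: dict[str, int] = {}
        for s in seqs:
            if i < len(s) and s[i] not in "-N":
                counts[s[i]] = counts.get(s[i], 0) + 1
        if counts:
            out.append(max(sorted(counts), key=lambda b: counts[b]))
    return "".join(out)


def simulate_null_locus(
    locus: OrthoLocus,
    config: PhyloNullConfig,
    min_arm: int = 5,
    max_spacer: int = 70,
) -> np.ndarray:
    """Form-count distribution under substitution-only evolution.

    The root is the majority-rule consensus of the observed locus; it is
    evolved down the tree ``n_reps`` times (seeded) with no
    template-switching move, and the perfect-IR form count of each
    replicate is returned.
    """
    present = {t: s for t, s in locus.taxa.items() if s is not None}
    tree = _as_tree(config.tree)
    tree_taxa = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    if not set(present) <= tree_taxa:
        raise ConfigurationError(
            f"locus taxa {sorted(set(present) - tree_taxa)} absent from tree")
    if len(present) < len(locus.taxa):
        tree = tree.extract_tree_with_taxa_labels(labels=sorted(present))
    obs_seqs = [s.upper() for s in present.values()]
    root = majority_root(obs_seqs)
    kappa = config.kappa if config.kappa is not None else estimate_kappa(obs_seqs)
    freqs = (config.freqs if config.freqs is not None
             else base_frequencies(obs_seqs))
    ev = _Evolver(tree, kappa, freqs)
    rng = np.random.default_rng(config.seed)
    root_codes = encode(root)
    leaves = ev.evolve_batch(root_codes, config.n_reps, rng)
    # scan each distinct leaf sequence exactly once, in one joined pass
    sp = min(max_spacer, root_codes.size)
    uniq_inv = {
        t: np.unique(mat, axis=0, return_inverse=True) for t, mat in leaves.items()
    }
    all_seqs: dict[str, None] = {}
    for uniq, _ in uniq_inv.values():
        for row in uniq:
            all_seqs.setdefault(decode(row))
    seq_list = list(all_seqs)
    keys = _batch_form_keys(seq_list, min_arm, sp)
    key_of = dict(zip(seq_list, keys))
    per_taxon_keys = {}
    for t, (uniq, inverse) in uniq_inv.items():
        uk = [key_of[decode(row)] for row in uniq]
        per_taxon_keys[t] = [uk[i] for i in inverse]
    counts = np.empty(config.n_reps, dtype=np.int64)
    taxa = list(per_taxon_keys)
    for rep in range(config.n_reps):
        forms = {per_taxon_keys[t][rep] for t in taxa}
        forms.discard(None)
        counts[rep] = len(forms)
    return counts


def locus_pvalue(observed_n_forms: int, null_counts: np.ndarray) -> float:
    """One-sided add-one-corrected empirical p-value."""
    null_counts = np.asarray(null_counts)
    if null_counts.size == 0:
        raise ValueError("null_counts must be non-empty")
    return float(
        (1 + int((null_counts >= observed_n_forms).sum())) / (1 + null_counts.size)
    )


# ---------------------------------------------------------------------------
# genome scan
# ---------------------------------------------------------------------------


def _ungapped_to_column(row: str) -> list[int]:
    """Map 0-based ungapped positions to alignment columns."""
    out = []
    for i, ch in enumerate(row):
        if ch != "-":
            out.append(i)
    return out


def genome_scan(
    ortho_msas: Mapping[str, Mapping[str, str]],
    tree,
    focal_taxon: str,
    config: Optional[PhyloNullConfig] = None,
    min_arm: int = 5,
    max_spacer: int = 70,
    margin: int = 0,
    alpha: float = 0.05,
    classify_quasi: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Profile and test every perfect IR of the focal genome's genes.

    ``ortho_msas`` maps gene id to {taxon: aligned sequence}; perfect IRs
    are detected in the degapped focal row, mapped to alignment columns,
    profiled across taxa and tested against the simulation null. Returns
    a per-locus table and gene-level aggregation counts.
    """
    base_seed = config.seed if config is not None else 0
    rows = []
    genes_with_ir = set()
    genes_with_multiform = set()
    genes_with_sig = set()
    locus_idx = 0
    for gene_id in sorted(ortho_msas):
        msa = ortho_msas[gene_id]
        if focal_taxon not in msa:
            continue
        focal_row = msa[focal_taxon].upper()
        focal_seq = focal_row.replace("-", "")
        col_of = _ungapped_to_column(focal_row)
        for ir in find_inverted_repeats(focal_seq, min_arm=min_arm, max_spacer=max_spacer):
            genes_with_ir.add(gene_id)
            c0 = col_of[ir.left_start - 1 - min(margin, ir.left_start - 1)]
            hi = min(ir.right_end - 1 + margin, len(focal_seq) - 1)
            c1 = col_of[hi] + 1
            locus_idx += 1
            locus = OrthoLocus(
                locus_id=f"{gene_id}:{ir.left_start}-{ir.right_end}",
                gene_id=gene_id,
                taxa={t: s[c0:c1] for t, s in msa.items()},
                columns=(c0, c1),
            )
            prof = count_ir_forms(
                locus, min_arm=min_arm, max_spacer=max_spacer,
                classify_quasi=classify_quasi,
            )
            if config is not None:
                cfg = PhyloNullConfig(
                    tree=tree, kappa=config.kappa, freqs=config.freqs,
                    n_reps=config.n_reps, seed=base_seed + locus_idx,
                )
                prof.null_counts = simulate_null_locus(
                    locus, cfg, min_arm=min_arm, max_spacer=max_spacer)
                prof.p_value = locus_pvalue(prof.n_forms, prof.null_counts)
            if prof.n_forms >= 2:
                genes_with_multiform.add(gene_id)
            if prof.p_value is not None and prof.p_value < alpha:
                genes_with_sig.add(gene_id)
            rows.append(
                {
                    "locus_id": locus.locus_id,
                    "gene_id": gene_id,
                    "n_forms": prof.n_forms,
                    "p_value": prof.p_value,
                    "status": ";".join(
                        f"{t}={prof.status[t]}" for t in sorted(prof.status)),
                }
            )
    table = pd.DataFrame(
        rows, columns=["locus_id", "gene_id", "n_forms", "p_value", "status"])
    n_forms = table["n_forms"] if len(table) else pd.Series([], dtype=int)
    agg = {
        "n_loci": int(len(table)),
        "n_genes_with_ir": len(genes_with_ir),
        "loci_ge2_forms": int((n_forms >= 2).sum()),
        "loci_ge3_forms": int((n_forms >= 3).sum()),
        "loci_ge4_forms": int((n_forms >= 4).sum()),
        "genes_ge2_forms": len(genes_with_multiform),
        "genes_with_significant_locus": len(genes_with_sig),
    }
    if config is not None and len(table):
        pv = table["p_value"].dropna()
        agg["loci_significant"] = int((pv < alpha).sum())
    return table, agg
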