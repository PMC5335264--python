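"""Synthetic SINE insertion histories on a species tree.

The generator draws a random ancestral genome at the root of a rooted
species tree, then walks every branch applying (i) nucleotide
substitutions under a single-parameter equal-rates model and (ii) SINE
insertions drawn from a small library of named rodent-like families.
With probability ``ils_prob`` an insertion on an internal branch sorts
incompletely: it is retained only by a random proper non-empty subset of
that branch's descendant taxa, emulating the persistence of an ancestral
insertion polymorphism through later speciations.

Every nucleotide carries a unique site identity, so true homology is
known exactly.  Pairwise alignments are therefore *reconstructed from
that known homology* rather than computed by an aligner: shared sites
are placed in aligned columns, lineage-specific sites opposite gaps.
Alignment blocks additionally drop windows whose aligned-column identity
falls below a threshold, emulating the failure of genome aligners to net
highly diverged sequence — this is what makes screen recall degrade as
the substitution rate grows.

Insertions are placed in disjoint genome slots (a uniformly chosen
unused slot, uniform position within the slot interior), so simulated
loci never overlap and always carry repeat-free flanks; SINE pile-ups
and nested insertions are deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import numpy as np

from .axt import AxtBlock, write_axt
from .repeatmasker import RepeatRecord, write_repeatmasker_out, zero_to_one

__all__ = [
    "DEFAULT_TREE",
    "FAMILY_LIBRARY",
    "InsertionEvent",
    "SimulatedDataset",
    "simulate",
    "emit_repeatmasker",
    "emit_axt",
    "truth_markers",
]

#: Rodent topology used throughout: beaver (Castoridae) and kangaroo rat
#: (Geomyoidea) unite as Castorimorpha inside the mouse-related clade;
#: guinea pig and ground squirrel are successively deeper outgroups.
#: Branch lengths are arbitrary time units.
DEFAULT_TREE = (
    "(((mouse:0.7,(beaver:0.35,kangaroo_rat:0.35)castorimorpha:0.35)"
    "mouse_related:0.35,guinea_pig:1.05)rodentia:0.35,ground_squirrel:1.4)root;"
)

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)


def _mock_consensus(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return _ALPHABET[rng.integers(0, 4, length)].tobytes().decode()


#: Mock SINE consensus library: (repeat class, consensus sequence) per
#: family, with SINE-typical lengths.  Sequences are fixed (seeded) so
#: datasets are reproducible across processes.
FAMILY_LIBRARY: dict[str, tuple[str, str]] = {
    "B1F": ("SINE/Alu", _mock_consensus(135, 101)),
    "PB1D7": ("SINE/Alu", _mock_consensus(120, 102)),
    "PB1D9": ("SINE/Alu", _mock_consensus(115, 103)),
    "PB1D10": ("SINE/Alu", _mock_consensus(110, 104)),
    "PB1D11": ("SINE/Alu", _mock_consensus(105, 105)),
    "SP-D-Geo": ("SINE/B2", _mock_consensus(160, 106)),
    "ID": ("SINE/ID", _mock_consensus(75, 107)),
}

_SLOT_WIDTH = 1000
_SLOT_MARGIN = 250


@dataclass(frozen=True)
class InsertionEvent:
    """One simulated SINE insertion with its ground truth."""

    event_id: int
    branch: tuple[str, ...]  # sorted leaf taxa below the branch
    position: int  # insertion point in the parent genome (0-based)
    family: str
    length: int
    carriers: frozenset[str]  # leaves actually carrying the element
    site_base: int  # first of the element's `length` consecutive site ids

    def __post_init__(self) -> None:
        if not self.carriers:
            raise ValueError("carrier set must be non-empty")
        if not self.carriers <= set(self.branch):
            raise ValueError("carriers must be descendants of the insertion branch")


@dataclass
class SimulatedDataset:
    """Genomes, per-taxon element coordinates, and the full event log."""

    tree: dendropy.Tree
    taxa: list[str]
    genomes: dict[str, str]
    site_ids: dict[str, np.ndarray]
    events: list[InsertionEvent]
    elements: dict[str, list[tuple[InsertionEvent, int, int]]]
    seed: int | None
    genome_length: int
    params: dict = field(default_factory=dict)

    def contig_lengths(self) -> dict[str, int]:
        return {taxon: len(seq) for taxon, seq in self.genomes.items()}

    def write_fasta(self, taxon: str, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f">{taxon}\n")
            seq = self.genomes[taxon]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def _leaf_labels(node: dendropy.Node) -> tuple[str, ...]:
    return tuple(sorted(leaf.taxon.label for leaf in node.leaf_iter()))


def _parse_tree(tree: "str | dendropy.Tree") -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    parsed = dendropy.Tree.get(data=tree, schema="newick", preserve_underscores=True)
    return parsed


def simulate(
    tree: "str | dendropy.Tree" = DEFAULT_TREE,
    genome_length: int = 100_000,
    insertion_rate: float = 2.0,
    subst_rate: float = 0.02,
    ils_prob: float = 0.05,
    seed: int | None = None,
    insertions: Mapping[tuple[str, ...], int] | None = None,
) -> SimulatedDataset:
    """Simulate SINE insertion histories along a species tree.

    Parameters
    ----------
    tree
        Newick string or dendropy tree; rooted, branch lengths > 0.
    genome_length
        Ancestral genome length in nt (>= 10x the longest element).
    insertion_rate
        Expected insertions per unit branch length (Poisson).
    subst_rate
        Substitutions per site per unit branch length (equal rates).
    ils_prob
        Probability that an internal-branch insertion sorts incompletely
        (carriers become a random proper non-empty subset of the
        branch's descendants).
    seed
        Seeds all randomness; equal seeds give bit-identical datasets.
    insertions
        Optional override: exact insertion counts per branch, keyed by
        the sorted tuple of descendant leaf names (e.g.
        ``{("beaver", "kangaroo_rat"): 6}``).  Branches without a key get
        zero insertions when the mapping is given.
    """
    if insertion_rate < 0 or subst_rate < 0 or not 0 <= ils_prob <= 1:
        raise ValueError("rates must be >= 0 and ils_prob in [0, 1]")
    t = _parse_tree(tree)
    leaves = sorted(leaf.taxon.label for leaf in t.leaf_node_iter())
    if len(leaves) != len(set(leaves)):
        raise ValueError("duplicate taxon labels in tree")
    max_element = max(len(seq) for _, seq in FAMILY_LIBRARY.values())
    if genome_length < 10 * max_element:
        raise ValueError(f"genome_length must be >= {10 * max_element}")
    for edge in t.preorder_edge_iter():
        if edge.head_node is not t.seed_node and (edge.length is None or edge.length <= 0):
            raise ValueError("all branch lengths must be > 0")

    rng = np.random.default_rng(seed)
    root_seq = rng.integers(0, 4, genome_length).astype(np.uint8)
    root_ids = np.arange(genome_length, dtype=np.int64)

    n_slots = genome_length // _SLOT_WIDTH
    free_slots = list(range(n_slots))
    families = sorted(FAMILY_LIBRARY)
    family_index = {
        name: np.frombuffer(FAMILY_LIBRARY[name][1].encode(), dtype=np.uint8)
        for name in families
    }
    base_to_index = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        base_to_index[b] = i

    events: list[InsertionEvent] = []
    next_site = genome_length
    leaf_state: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def descend(node: dendropy.Node, ids: np.ndarray, seq: np.ndarray) -> None:
        nonlocal next_site
        for child in node.child_nodes():
            c_ids = ids.copy()
            c_seq = seq.copy()
            blen = child.edge.length
            # substitutions first: they act on sequence inherited from the parent
            p_sub = min(1.0, subst_rate * blen)
            if p_sub > 0:
                n_sub = rng.binomial(len(c_seq), p_sub)
                if n_sub:
                    pos = rng.choice(len(c_seq), size=n_sub, replace=False)
                    c_seq[pos] = (c_seq[pos] + rng.integers(1, 4, n_sub).astype(np.uint8)) % 4
            branch_key = _leaf_labels(child)
            if insertions is not None:
                n_ins = int(insertions.get(branch_key, 0))
            else:
                n_ins = int(rng.poisson(insertion_rate * blen))
            for _ in range(n_ins):
                if not free_slots:
                    raise ValueError(
                        "too many insertions for the genome length: no free slots left"
                    )
                slot = free_slots.pop(int(rng.integers(len(free_slots))))
                low = slot * _SLOT_WIDTH + _SLOT_MARGIN
                high = (slot + 1) * _SLOT_WIDTH - _SLOT_MARGIN - max_element
                anchor = int(rng.integers(low, high))  # root-coordinate site id
                family = families[int(rng.integers(len(families)))]
                consensus = family_index[family]
                idx = int(np.nonzero(c_ids == anchor)[0][0])
                new_ids = np.arange(next_site, next_site + len(consensus), dtype=np.int64)
                new_seq = base_to_index[consensus]
                c_ids = np.concatenate([c_ids[:idx], new_ids, c_ids[idx:]])
                c_seq = np.concatenate([c_seq[:idx], new_seq, c_seq[idx:]])
                descendants = set(branch_key)
                carriers = frozenset(descendants)
                if len(descendants) > 1 and rng.random() < ils_prob:
                    ordered = sorted(descendants)
                    while True:
                        mask = rng.random(len(ordered)) < 0.5
                        chosen = frozenset(x for x, m in zip(ordered, mask) if m)
                        if chosen and chosen != carriers:
                            carriers = chosen
                            break
                events.append(
                    InsertionEvent(
                        event_id=len(events),
                        branch=branch_key,
                        position=idx,
                        family=family,
                        length=len(consensus),
                        carriers=carriers,
                        site_base=int(new_ids[0]),
                    )
                )
                next_site += len(consensus)
            if child.is_leaf():
                leaf_state[child.taxon.label] = (c_ids, c_seq)
            else:
                descend(child, c_ids, c_seq)

    descend(t.seed_node, root_ids, root_seq)

    # resolve incomplete lineage sorting: strip events from non-carriers
    genomes: dict[str, str] = {}
    site_ids: dict[str, np.ndarray] = {}
    elements: dict[str, list[tuple[InsertionEvent, int, int]]] = {}
    for taxon in leaves:
        ids, seq = leaf_state[taxon]
        drop = np.zeros(len(ids), dtype=bool)
        for ev in events:
            if taxon not in ev.carriers:
                drop |= (ids >= ev.site_base) & (ids < ev.site_base + ev.length)
        if drop.any():
            ids = ids[~drop]
            seq = seq[~drop]
        site_ids[taxon] = ids
        genomes[taxon] = _ALPHABET[seq].tobytes().decode()
        copies: list[tuple[InsertionEvent, int, int]] = []
        for ev in events:
            if taxon in ev.carriers:
                hit = np.nonzero(ids == ev.site_base)[0]
                start = int(hit[0])
                copies.append((ev, start, start + ev.length))
        copies.sort(key=lambda x: x[1])
        elements[taxon] = copies

    return SimulatedDataset(
        tree=t,
        taxa=leaves,
        genomes=genomes,
        site_ids=site_ids,
        events=events,
        elements=elements,
        seed=seed,
        genome_length=genome_length,
        params={
            "insertion_rate": insertion_rate,
            "subst_rate": subst_rate,
            "ils_prob": ils_prob,
            "insertions": {"/".join(k): v for k, v in insertions.items()} if insertions else None,
        },
    )


def emit_repeatmasker(dataset: SimulatedDataset, taxon: str) -> str:
    """RepeatMasker-style ``.out`` table for one taxon's genome.

    One row per element copy, coordinates in the mutated genome (1-based
    inclusive in the file), divergence computed against the family
    consensus.
    """
    genome = dataset.genomes[taxon]
    records = []
    for ev, start, end in dataset.elements[taxon]:
        observed = genome[start:end]
        consensus = FAMILY_LIBRARY[ev.family][1]
        mismatches = sum(1 for a, b in zip(observed, consensus) if a != b)
        pct_div = round(100.0 * mismatches / ev.length, 1)
        begin1, end1 = zero_to_one(start, end)
        records.append(
            RepeatRecord(
                sw_score=max(1, 10 * ev.length - 50 * mismatches),
                pct_div=pct_div,
                pct_del=0.0,
                pct_ins=0.0,
                seq_id=taxon,
                begin=begin1,
                end=end1,
                left_remaining=len(genome) - end,
                strand="+",
                repeat_name=ev.family,
                repeat_class=FAMILY_LIBRARY[ev.family][0],
                rep_begin=1,
                rep_end=ev.length,
                rep_left=0,
                element_id=ev.event_id,
            )
        )
    return write_repeatmasker_out(records)


def _pairwise_columns(
    ids_a: np.ndarray, ids_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Column maps of the homology-true pairwise alignment.

    Returns (col_a, col_b): per alignment column, the index into each
    genome or -1 for a gap.  Shared sites occupy aligned columns in their
    (common) relative order; between anchors, A-only sites precede B-only
    sites.
    """
    in_b = np.isin(ids_a, ids_b)
    in_a = np.isin(ids_b, ids_a)
    col_a: list[int] = []
    col_b: list[int] = []
    i = j = 0
    n_a, n_b = len(ids_a), len(ids_b)
    while i < n_a or j < n_b:
        if i < n_a and not in_b[i]:
            col_a.append(i)
            col_b.append(-1)
            i += 1
        elif j < n_b and not in_a[j]:
            col_a.append(-1)
            col_b.append(j)
            j += 1
        else:
            # both shared: identical sites in identical order
            col_a.append(i)
            col_b.append(j)
            i += 1
            j += 1
    return np.asarray(col_a, dtype=np.int64), np.asarray(col_b, dtype=np.int64)


def emit_axt(
    dataset: SimulatedDataset,
    ref_taxon: str,
    query_taxon: str,
    block_length: int | None = None,
    min_identity: float = 0.5,
    identity_window: int = 101,
) -> str:
    """AXT text for a reference/query pair, reconstructed from known homology.

    Aligned columns whose local identity (over aligned columns within a
    sliding window) drops below ``min_identity`` are treated as
    unalignable and removed, splitting the alignment into blocks; gap
    runs from insertions never split a block.  ``block_length`` further
    chunks blocks at aligned columns.  Strand is always ``+``.
    """
    ids_r = dataset.site_ids[ref_taxon]
    ids_q = dataset.site_ids[query_taxon]
    seq_r = dataset.genomes[ref_taxon]
    seq_q = dataset.genomes[query_taxon]
    col_r, col_q = _pairwise_columns(ids_r, ids_q)
    n_cols = len(col_r)
    aligned = (col_r >= 0) & (col_q >= 0)

    keep = np.ones(n_cols, dtype=bool)
    if min_identity > 0:
        r_chars = np.frombuffer(seq_r.encode(), dtype="S1")
        q_chars = np.frombuffer(seq_q.encode(), dtype="S1")
        match = np.zeros(n_cols, dtype=np.float64)
        match[aligned] = (
            r_chars[col_r[aligned]] == q_chars[col_q[aligned]]
        ).astype(np.float64)
        half = identity_window // 2
        csum_match = np.concatenate([[0.0], np.cumsum(match)])
        csum_aligned = np.concatenate([[0.0], np.cumsum(aligned.astype(np.float64))])
        idx = np.arange(n_cols)
        lo = np.maximum(0, idx - half)
        hi = np.minimum(n_cols, idx + half + 1)
        window_aligned = csum_aligned[hi] - csum_aligned[lo]
        window_match = csum_match[hi] - csum_match[lo]
        with np.errstate(invalid="ignore"):
            identity = np.where(window_aligned > 0, window_match / window_aligned, 1.0)
        keep[aligned & (identity < min_identity)] = False

    blocks: list[AxtBlock] = []
    index = 0
    start = 0
    while start < n_cols:
        if not keep[start]:
            start += 1
            continue
        stop = start
        while stop < n_cols and keep[stop]:
            stop += 1
        for chunk_start, chunk_stop in _chunk(start, stop, aligned, block_length):
            block = _make_block(
                index, ref_taxon, query_taxon, seq_r, seq_q, col_r, col_q, chunk_start, chunk_stop
            )
            if block is not None:
                blocks.append(block)
                index += 1
        start = stop
    return write_axt(blocks)


def _chunk(start: int, stop: int, aligned: np.ndarray, block_length: int | None):
    if block_length is None or stop - start <= block_length:
        yield start, stop
        return
    cur = start
    while cur < stop:
        target = min(cur + block_length, stop)
        # extend to the next aligned column so chunks never split a gap run
        while target < stop and not aligned[target]:
            target += 1
        yield cur, target
        cur = target


def _make_block(
    index: int,
    ref_name: str,
    query_name: str,
    seq_r: str,
    seq_q: str,
    col_r: np.ndarray,
    col_q: np.ndarray,
    start: int,
    stop: int,
) -> AxtBlock | None:
    r_cols = col_r[start:stop]
    q_cols = col_q[start:stop]
    r_idx = r_cols[r_cols >= 0]
    q_idx = q_cols[q_cols >= 0]
    if len(r_idx) == 0 or len(q_idx) == 0:
        return None
    ref_aln = "".join(seq_r[i] if i >= 0 else "-" for i in r_cols)
    query_aln = "".join(seq_q[j] if j >= 0 else "-" for j in q_cols)
    score = sum(1 for a, b in zip(ref_aln, query_aln) if a == b and a != "-")
    return AxtBlock(
        index=index,
        ref_name=ref_name,
        ref_start=int(r_idx[0]),
        ref_end=int(r_idx[-1]) + 1,
        query_name=query_name,
        query_start=int(q_idx[0]),
        query_end=int(q_idx[-1]) + 1,
        query_strand="+",
        score=score,
        ref_aln=ref_aln,
        query_aln=query_aln,
    )


def truth_markers(dataset: SimulatedDataset, clade: Iterable[str]) -> list[InsertionEvent]:
    """Events diagnostic for exactly this clade (carriers == clade)."""
    target = frozenset(clade)
    if not target:
        raise ValueError("clade must be non-empty")
    return [ev for ev in dataset.events if ev.carriers == target]


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> None:
    """Write all taxa's FASTA, RepeatMasker tables, and all AXT pairs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for taxon in dataset.taxa:
        dataset.write_fasta(taxon, outdir / f"{taxon}.fa")
        (outdir / f"{taxon}.rm.out").write_text(emit_repeatmasker(dataset, taxon))
    for ref in dataset.taxa:
        for query in dataset.taxa:
            if ref == query:
                continue
            (outdir / f"{ref}.vs.{query}.axt").write_text(emit_axt(dataset, ref, query))
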