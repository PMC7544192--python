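"""De novo assembly of plasmid-scale circular sequences.

A single-k de Bruijn assembler tuned for the plasmid regime: targets of a
few kb, coverage capped in the hundreds, and the expectation that a clean
sample yields exactly ONE circular contig.  The graph is built on
canonical k-mers (strand-independent), cleaned by tip clipping and simple
bubble popping (keeping the higher-depth branch, which also resolves
SNP/indel heterogeneity between a primary plasmid and a minority
contaminant), and whole components whose median depth falls below a
fraction of the deepest component's median are discarded — this is what
suppresses low-fraction unrelated contaminants.  A component in which
every k-mer has exactly one predecessor and one successor is a simple
cycle and is emitted as a circular contig with the redundant (k-1)-base
overlap removed and a canonical rotation applied, so output is stable
across runs.

All tie-breaks are lexicographic on packed k-mer values or contig
sequences, making assembly fully deterministic.  Paired-end information
is not used for scaffolding: at k=31 plasmid-scale targets without
repeats longer than k assemble from single-end graph structure alone;
repeat-rich plasmids are a documented limitation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from . import _kmers
from .seqcore import Contig, ReadSet, canonical_rotation

_BASES = "ACGT"


@dataclass
class AssemblyParams:
    """De Bruijn graph parameters.

    ``k`` must be odd (canonical-strand disambiguation) and below the
    retained read length.  ``min_kmer_count`` drops sequencing-error
    k-mers before graph construction.  ``rel_depth_floor`` discards graph
    components whose median k-mer depth is below this fraction of the
    deepest component's median — a minority unrelated contaminant forms
    its own shallow component and is removed here.  ``tip_len_max`` is
    the longest dead-end path (in k-mers) clipped as a tip; None means 2k.
    """

    k: int = 31
    min_kmer_count: int = 3
    rel_depth_floor: float = 0.25
    tip_len_max: int | None = None
    max_simplify_rounds: int = 10

    def __post_init__(self) -> None:
        if self.k < 3 or self.k % 2 == 0 or self.k > 31:
            raise ValueError("k must be odd, in [3, 31]")
        if self.min_kmer_count < 1:
            raise ValueError("min_kmer_count must be >= 1")
        if not 0 <= self.rel_depth_floor < 1:
            raise ValueError("rel_depth_floor must be in [0, 1)")

    @property
    def effective_tip_len(self) -> int:
        return self.tip_len_max if self.tip_len_max is not None else 2 * self.k


@dataclass
class AssemblyResult:
    """Contigs plus the parameters and read count that produced them."""

    contigs: list[Contig]
    params_used: AssemblyParams
    total_reads_used: int = 0

    @property
    def n_contigs(self) -> int:
        return len(self.contigs)


def count_kmers(rs: ReadSet, k: int) -> dict[str, int]:
    """Canonical k-mer counts over both mates of every pair.

    Counts are strand-independent (each window contributes the
    lexicographically smaller of itself and its reverse complement);
    windows containing N are skipped.
    """
    seqs: list[str] = []
    for pair in rs:
        seqs.append(pair.r1_seq)
        seqs.append(pair.r2_seq)
    kmers, counts = _kmers.canonical_kmer_counts(seqs, k)
    return {
        _kmers.kmer_to_str(v, k): int(c)
        for v, c in zip(kmers.tolist(), counts.tolist())
    }


def auto_k(rs: ReadSet, default: int = 31) -> int:
    """Pick k from the shortest retained read.

    Returns ``default`` when every read is longer than it, otherwise the
    largest odd k <= (min read length - 1), never below 15.
    """
    if len(rs) == 0:
        raise ValueError("empty ReadSet")
    min_len = min(min(len(p.r1_seq), len(p.r2_seq)) for p in rs)
    if min_len < 16:
        raise ValueError(f"shortest read ({min_len} nt) too short to pick k >= 15")
    if min_len > default:
        return default
    k = min_len - 1
    if k % 2 == 0:
        k -= 1
    return max(k, 15)


# ---------------------------------------------------------------------------
# Graph internals.  An oriented k-mer is the tuple (value, rc_value) of its
# packed forward and reverse-complement encodings; its canonical id is
# min(value, rc_value).  Carrying both values makes neighbor queries and
# walks O(1) per step with no per-step reverse complementation.


class _DeBruijn:
    def __init__(self, kmers: np.ndarray, counts: np.ndarray, k: int):
        self.k = k
        self.mask = (1 << (2 * k)) - 1
        self.shift = 2 * (k - 1)
        keys = kmers.tolist()
        self.cnt: dict[int, int] = dict(zip(keys, counts.tolist()))
        self.rc: dict[int, int] = dict(
            zip(keys, _kmers.revcomp_int(kmers, k).tolist())
        )

    def __len__(self) -> int:
        return len(self.cnt)

    def fwd(self, v: int, rv: int) -> list[tuple[int, int]]:
        out = []
        for x in range(4):
            w = ((v << 2) | x) & self.mask
            rw = (rv >> 2) | ((3 - x) << self.shift)
            if (w if w < rw else rw) in self.cnt:
                out.append((w, rw))
        return out

    def bwd(self, v: int, rv: int) -> list[tuple[int, int]]:
        out = []
        for x in range(4):
            w = (v >> 2) | (x << self.shift)
            rw = ((rv << 2) | (3 - x)) & self.mask
            if (w if w < rw else rw) in self.cnt:
                out.append((w, rw))
        return out

    def oriented(self, canon: int) -> tuple[int, int]:
        return canon, self.rc[canon]

    def remove(self, canons: Iterable[int]) -> None:
        for c in canons:
            del self.cnt[c]
            del self.rc[c]


@dataclass
class _Unitig:
    nodes: list[tuple[int, int]]  # oriented k-mers along the walk
    canons: set[int] = field(default_factory=set)
    circular: bool = False

    def mean_count(self, g: _DeBruijn) -> float:
        return float(np.mean([g.cnt[min(n)] for n in self.nodes]))


def _build_unitigs(g: _DeBruijn) -> list[_Unitig]:
    """Compact maximal non-branching paths; deterministic start order."""
    visited: set[int] = set()
    unitigs: list[_Unitig] = []
    for c in sorted(g.cnt):
        if c in visited:
            continue
        start = g.oriented(c)
        nodes = [start]
        canons = {c}
        circular = False
        cur = start
        while True:  # extend forward
            outs = g.fwd(*cur)
            if len(outs) != 1:
                break
            nxt = outs[0]
            if len(g.bwd(*nxt)) != 1:
                break
            if nxt == start:
                circular = True
                break
            cn = min(nxt)
            if cn in canons:
                break  # odd structure (e.g. mobius-like); stop cleanly
            nodes.append(nxt)
            canons.add(cn)
            cur = nxt
        if not circular:
            cur = start
            while True:  # extend backward
                ins = g.bwd(*cur)
                if len(ins) != 1:
                    break
                prv = ins[0]
                if len(g.fwd(*prv)) != 1:
                    break
                cn = min(prv)
                if cn in canons:
                    break
                nodes.insert(0, prv)
                canons.add(cn)
                cur = prv
        visited |= canons
        unitigs.append(_Unitig(nodes=nodes, canons=canons, circular=circular))
    return unitigs


def _clip_tips(g: _DeBruijn, unitigs: list[_Unitig], tip_len_max: int) -> int:
    """Remove short dead-end paths attached at exactly one end."""
    removed = 0
    for u in unitigs:
        if u.circular or len(u.nodes) > tip_len_max:
            continue
        dead_b = len(g.bwd(*u.nodes[0])) == 0
        dead_f = len(g.fwd(*u.nodes[-1])) == 0
        if dead_b != dead_f:  # attached at one end only
            if all(c in g.cnt for c in u.canons):
                g.remove(u.canons)
                removed += 1
    return removed


def _pop_bubbles(g: _DeBruijn, unitigs: list[_Unitig]) -> int:
    """Pop simple bubbles: parallel unitigs sharing both anchor k-mers.

    Branches may have very different lengths (an indel between a primary
    plasmid and its contaminant is a bubble whose arms differ by the indel
    size); the lower-mean-depth arm is always the one removed, with ties
    broken toward keeping the lexicographically smaller arm sequence.
    """
    groups: dict[frozenset, list[_Unitig]] = {}
    for u in unitigs:
        if u.circular:
            continue
        ins = g.bwd(*u.nodes[0])
        outs = g.fwd(*u.nodes[-1])
        if len(ins) != 1 or len(outs) != 1:
            continue
        key = frozenset((min(ins[0]), min(outs[0])))
        groups.setdefault(key, []).append(u)
    removed = 0
    for arms in groups.values():
        if len(arms) < 2:
            continue
        ranked = sorted(
            arms, key=lambda u: (-u.mean_count(g), _spell_linear(u, g.k))
        )
        for u in ranked[1:]:
            if all(c in g.cnt for c in u.canons):
                g.remove(u.canons)
                removed += 1
    return removed


def _components(g: _DeBruijn) -> list[list[int]]:
    seen: set[int] = set()
    comps: list[list[int]] = []
    for c in sorted(g.cnt):
        if c in seen:
            continue
        stack = [c]
        comp = []
        seen.add(c)
        while stack:
            v = stack.pop()
            comp.append(v)
            ori = g.oriented(v)
            for w, rw in g.fwd(*ori) + g.bwd(*ori):
                cn = w if w < rw else rw
                if cn not in seen:
                    seen.add(cn)
                    stack.append(cn)
        comps.append(comp)
    return comps


def _drop_shallow_components(g: _DeBruijn, floor: float) -> None:
    comps = _components(g)
    if len(comps) <= 1 or floor <= 0:
        return
    medians = [float(np.median([g.cnt[c] for c in comp])) for comp in comps]
    ref = max(medians)
    for comp, med in zip(comps, medians):
        if med < floor * ref:
            g.remove(comp)


def _first_base(node: tuple[int, int], k: int) -> str:
    return _BASES[(node[0] >> (2 * (k - 1))) & 3]


def _spell_linear(u: _Unitig, k: int) -> str:
    s = [_kmers.kmer_to_str(u.nodes[0][0], k)]
    for v, _ in u.nodes[1:]:
        s.append(_BASES[v & 3])
    return "".join(s)


def _emit_contigs(g: _DeBruijn, k: int) -> list[Contig]:
    contigs: list[Contig] = []
    for comp in _components(g):
        comp_set = set(comp)
        simple_cycle = True
        for c in comp:
            ori = g.oriented(c)
            if len(g.fwd(*ori)) != 1 or len(g.bwd(*ori)) != 1:
                simple_cycle = False
                break
        if simple_cycle and len(comp) >= 2:
            start = g.oriented(min(comp))
            walk = [start]
            cur = g.fwd(*start)[0]
            while cur != start and len(walk) <= len(comp):
                walk.append(cur)
                cur = g.fwd(*cur)[0]
            if cur == start and len(walk) == len(comp):
                seq = "".join(_first_base(n, k) for n in walk)
                depth = float(np.mean([g.cnt[c] for c in comp]))
                contigs.append(
                    Contig(seq=canonical_rotation(seq), circular=True, mean_depth=depth)
                )
                continue
        # linear emission: compact the component's unitigs
        sub = _DeBruijn.__new__(_DeBruijn)
        sub.k, sub.mask, sub.shift = g.k, g.mask, g.shift
        sub.cnt = {c: g.cnt[c] for c in sorted(comp_set)}
        sub.rc = {c: g.rc[c] for c in sorted(comp_set)}
        for u in _build_unitigs(sub):
            if u.circular:
                seq = "".join(_first_base(n, k) for n in u.nodes)
                seq = canonical_rotation(seq)
            else:
                seq = _spell_linear(u, k)
            contigs.append(
                Contig(seq=seq, circular=u.circular, mean_depth=u.mean_count(g))
            )
    contigs.sort(key=lambda c: (-len(c.seq), c.seq))
    return contigs


def assemble(rs: ReadSet, ap: AssemblyParams | None = None) -> AssemblyResult:
    """Assemble a read set into (ideally) one circular plasmid contig.

    Pipeline: canonical k-mer counting -> abundance threshold -> tip
    clipping and bubble popping to a fixed point -> shallow-component
    drop -> contig emission.  An empty graph after pruning yields an
    empty contig list (NO_ASSEMBLY), not an exception.
    """
    ap = ap or AssemblyParams()
    if len(rs) == 0:
        raise ValueError("cannot assemble an empty ReadSet")
    seqs: list[str] = []
    for pair in rs:
        seqs.append(pair.r1_seq)
        seqs.append(pair.r2_seq)
    kmers, counts = _kmers.canonical_kmer_counts(seqs, ap.k)
    keep = counts >= ap.min_kmer_count
    kmers, counts = kmers[keep], counts[keep]
    if kmers.size == 0:
        return AssemblyResult(contigs=[], params_used=ap, total_reads_used=len(seqs))

    g = _DeBruijn(kmers, counts, ap.k)
    for _ in range(ap.max_simplify_rounds):
        unitigs = _build_unitigs(g)
        n_tips = _clip_tips(g, unitigs, ap.effective_tip_len)
        if n_tips:
            unitigs = _build_unitigs(g)
        n_bub = _pop_bubbles(g, unitigs)
        if n_tips == 0 and n_bub == 0:
            break
    _drop_shallow_components(g, ap.rel_depth_floor)
    if len(g) == 0:
        return AssemblyResult(contigs=[], params_used=ap, total_reads_used=len(seqs))
    contigs = _emit_contigs(g, ap.k)
    return AssemblyResult(contigs=contigs, params_used=ap, total_reads_used=len(seqs))
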