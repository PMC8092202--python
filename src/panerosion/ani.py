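"""Average nucleotide identity (ANI) and cutoff clustering.

Follows the orthologous-fragment ANI scheme: each assembly is cut into
consecutive non-overlapping 1020-bp fragments, fragments are matched
across genomes by shared 15-mers (both strands), matched pairs are
globally aligned, and the ANI of a genome pair is the mean percent
identity over *reciprocal best* fragment pairs. Genomes are then clustered
by single linkage at a percent-identity cutoff (95% species boundary by
default; an 85% subgroup variant is exposed the same way).
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

DEFAULT_FRAGMENT = 1020
KMER = 15
COVERAGE_FLOOR = 0.70

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class AniMatrix:
    genome_ids: list[str]
    values: np.ndarray  # percent identities; NaN = no reciprocal fragment pairs

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.genome_ids), len(self.genome_ids)):
            raise ValueError("matrix shape mismatch")
        with np.errstate(invalid="ignore"):
            if np.nanmax(np.abs(v - v.T)) > 1e-9:
                raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(v), 100.0):
            raise ValueError("diagonal must be 100")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genome_ids, columns=self.genome_ids)


@dataclass
class ClusterAssignment:
    cutoff: float
    labels: dict[str, int]
    linkage: str = "single"

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))


def fragment_genome(assembly: dict[str, str], length: int = DEFAULT_FRAGMENT) -> list[tuple[str, str]]:
    """Cut contigs into consecutive non-overlapping windows of exactly ``length`` bp.

    The trailing remainder of each contig is discarded. Fragment ids are
    ``contig:start-end`` with 0-based half-open coordinates.
    """
    if not assembly:
        raise ValueError("empty assembly")
    fragments = []
    for contig_id in sorted(assembly):
        seq = assembly[contig_id]
        for start in range(0, len(seq) - length + 1, length):
            fragments.append((f"{contig_id}:{start}-{start + length}", seq[start : start + length]))
    if not fragments:
        raise ValueError("genome too short for ANI")
    return fragments


def _kmer_index(fragments: list[tuple[str, str]], k: int = KMER) -> dict[str, set[int]]:
    index: dict[str, set[int]] = {}
    for i, (_, seq) in enumerate(fragments):
        for j in range(0, len(seq) - k + 1):
            index.setdefault(seq[j : j + k], set()).add(i)
    return index


def _fragment_identity(a: str, b: str) -> tuple[float, int]:
    """Percent identity and matched-column count of a global fragment alignment."""
    res = edlib.align(a, b, mode="NW", task="path")
    cigar = res["cigar"]
    matched = 0
    aligned = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        aligned += n
        if ch in "=X":
            matched += n
    identity = 100.0 * (aligned - res["editDistance"]) / aligned if aligned else 0.0
    return identity, matched


def _best_hits(frags_a, frags_b, index_b, length):
    """For each fragment of A: (best B fragment index, identity) or None."""
    hits = {}
    for i, (_, seq) in enumerate(frags_a):
        best = None
        for oriented in (seq, revcomp(seq)):
            votes: dict[int, int] = {}
            for j in range(0, len(oriented) - KMER + 1, KMER):  # non-overlapping seed stride
                for cand in index_b.get(oriented[j : j + KMER], ()):
                    votes[cand] = votes.get(cand, 0) + 1
            if not votes:
                continue
            cand = min(votes, key=lambda c: (-votes[c], c))
            identity, matched = _fragment_identity(oriented, frags_b[cand][1])
            if matched < COVERAGE_FLOOR * length:
                continue
            if best is None or identity > best[1] or (identity == best[1] and cand < best[0]):
                best = (cand, identity)
        if best is not None:
            hits[i] = best
    return hits


def pairwise_ani(
    genome_a: dict[str, str], genome_b: dict[str, str], length: int = DEFAULT_FRAGMENT
) -> float:
    """ANI between two assemblies (percent); NaN if no reciprocal pairs pass.

    Symmetric by construction: the value is the mean identity over
    reciprocal best fragment pairs.
    """
    frags_a = fragment_genome(genome_a, length)
    frags_b = fragment_genome(genome_b, length)
    index_a = _kmer_index(frags_a)
    index_b = _kmer_index(frags_b)
    hits_ab = _best_hits(frags_a, frags_b, index_b, length)
    hits_ba = _best_hits(frags_b, frags_a, index_a, length)
    identities = []
    for i, (j, ident) in sorted(hits_ab.items()):
        back = hits_ba.get(j)
        if back is not None and back[0] == i:
            identities.append((ident + back[1]) / 2.0)
    if not identities:
        return float("nan")
    return float(np.mean(identities))


def ani_matrix(genomes: dict[str, dict[str, str]], length: int = DEFAULT_FRAGMENT) -> AniMatrix:
    """Symmetric pairwise ANI matrix over a set of assemblies."""
    ids = sorted(genomes)
    n = len(ids)
    values = np.full((n, n), np.nan)
    np.fill_diagonal(values, 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            ani = pairwise_ani(genomes[ids[i]], genomes[ids[j]], length)
            values[i, j] = values[j, i] = ani
    return AniMatrix(genome_ids=ids, values=values)


def threshold_cluster(matrix: AniMatrix, cutoff: float) -> ClusterAssignment:
    """Single-linkage clustering: genomes merge iff pairwise ANI >= cutoff.

    Clusters are connected components of the >=cutoff graph; missing
    (NaN) values never merge. Labels are 0-based, ordered by each
    cluster's first genome id.
    """
    if not (0.0 < cutoff <= 100.0):
        raise ValueError("cutoff must be in (0, 100]")
    ids = matrix.genome_ids
    parent = {g: g for g in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(ids):
        for j in range(i + 1, len(ids)):
            v = matrix.values[i, j]
            if np.isfinite(v) and v >= cutoff:
                ra, rb = find(a), find(ids[j])
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
    roots = []
    labels = {}
    for g in sorted(ids):
        r = find(g)
        if r not in roots:
            roots.append(r)
        labels[g] = roots.index(r)
    return ClusterAssignment(cutoff=cutoff, labels=labels)
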