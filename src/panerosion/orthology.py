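"""Orthologous-group construction and annotation-based refinement.

Raw gene families are built from all-vs-all protein local alignments as
connected components of the reciprocal-best-hit (RBH) graph, a deliberately
simple stand-in for a full Markov-clustering orthology engine; externally
computed raw groups can be ingested instead (:func:`read_raw_groups_tsv`).

The refinement step then partitions every raw group by exact annotation
(product-string) equality: two genes belong to the same refined orthologous
group only if they are in the same raw group *and* carry the same
annotation (whitespace-trimmed, case-sensitive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._alignment import local_protein_identity

logger = logging.getLogger(__name__)

#: minimum local-alignment score for a hit to enter the table
SCORE_FLOOR = 50.0


@dataclass
class GeneRecord:
    """One annotated coding sequence."""

    genome_id: str
    gene_id: str
    annotation: str
    nt_seq: str
    aa_seq: str
    status: str = "unclassified"  # unclassified | intact | pseudogene

    @property
    def key(self) -> tuple[str, str]:
        return (self.genome_id, self.gene_id)


@dataclass
class OrthoGroup:
    group_id: str
    members: list[GeneRecord]
    cog_categories: set[str] = field(default_factory=set)

    @property
    def genome_ids(self) -> set[str]:
        return {m.genome_id for m in self.members}


def all_vs_all_scores(records: list[GeneRecord], score_floor: float = SCORE_FLOOR) -> pd.DataFrame:
    """Best local-alignment hits for every ordered cross-genome gene pair.

    Returns a DataFrame with columns query_genome, query, subject_genome,
    subject, score, identity — one row per ordered cross-genome pair whose
    local BLOSUM62 alignment score reaches ``score_floor``. Self-genome
    pairs are excluded.
    """
    if not records:
        raise ValueError("no records")
    genomes = {r.genome_id for r in records}
    if len(genomes) < 2:
        raise ValueError("all-vs-all requires records from >= 2 genomes")
    ordered = sorted(records, key=lambda r: r.key)
    rows = []
    for q in ordered:
        for s in ordered:
            if s.genome_id == q.genome_id:
                continue
            score, identity = local_protein_identity(q.aa_seq, s.aa_seq)
            if score >= score_floor:
                rows.append((q.genome_id, q.gene_id, s.genome_id, s.gene_id, score, identity))
    return pd.DataFrame(
        rows, columns=["query_genome", "query", "subject_genome", "subject", "score", "identity"]
    )


def _best_hits(hits: pd.DataFrame) -> dict[tuple[str, str, str], str]:
    """(query_genome, query, subject_genome) -> best subject gene.

    Ties broken by higher identity, then lexicographic subject id.
    """
    best: dict[tuple[str, str, str], tuple[float, float, str]] = {}
    for row in hits.itertuples(index=False):
        key = (row.query_genome, row.query, row.subject_genome)
        cand = (row.score, row.identity, row.subject)
        cur = best.get(key)
        if cur is None:
            best[key] = cand
            continue
        # prefer higher score, then higher identity, then smaller subject id
        if (cand[0], cand[1], _neg_str(cand[2])) > (cur[0], cur[1], _neg_str(cur[2])):
            best[key] = cand
    return {k: v[2] for k, v in best.items()}


class _neg_str:
    """Wrapper inverting string comparison (so min id wins inside max)."""

    __slots__ = ("s",)

    def __init__(self, s: str):
        self.s = s

    def __lt__(self, other: "_neg_str") -> bool:
        return self.s > other.s

    def __gt__(self, other: "_neg_str") -> bool:
        return self.s < other.s

    def __eq__(self, other) -> bool:
        return self.s == other.s


class _UnionFind:
    def __init__(self):
        self.parent: dict = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def rbh_edges(hits: pd.DataFrame) -> set[frozenset]:
    """Reciprocal-best-hit edges: A is B's best hit in A's genome and vice versa."""
    best = _best_hits(hits)
    genome_of = {}
    for row in hits.itertuples(index=False):
        genome_of[row.query] = row.query_genome
        genome_of[row.subject] = row.subject_genome
    edges = set()
    for (qg, q, sg), s in best.items():
        back = best.get((sg, s, qg))
        if back == q:
            edges.add(frozenset({(qg, q), (sg, s)}))
    return edges


def rbh_cluster(hits: pd.DataFrame, records: list[GeneRecord]) -> dict[str, list[GeneRecord]]:
    """Raw groups = connected components of the RBH graph.

    Every record appears in exactly one raw group; records with no RBH edge
    form singletons. Group ids are ``RAW`` + running index over groups
    ordered by their smallest member key.
    """
    uf = _UnionFind()
    for rec in records:
        uf.find(rec.key)
    for edge in rbh_edges(hits):
        a, b = tuple(edge)
        uf.union(a, b)
    components: dict = {}
    for rec in records:
        components.setdefault(uf.find(rec.key), []).append(rec)
    groups = {}
    for i, root in enumerate(sorted(components)):
        members = sorted(components[root], key=lambda r: r.key)
        groups[f"RAW{i:05d}"] = members
    return groups


def read_raw_groups_tsv(path: str | Path, records: list[GeneRecord]) -> dict[str, list[GeneRecord]]:
    """Ingest externally computed raw groups (group_id, genome_id, gene_id)."""
    df = pd.read_csv(path, sep="\t")
    by_key = {r.key: r for r in records}
    groups: dict[str, list[GeneRecord]] = {}
    for row in df.itertuples(index=False):
        rec = by_key.get((row.genome_id, row.gene_id))
        if rec is None:
            logger.warning("raw group member %s/%s has no record; skipped", row.genome_id, row.gene_id)
            continue
        groups.setdefault(str(row.group_id), []).append(rec)
    return {g: sorted(m, key=lambda r: r.key) for g, m in groups.items()}


def refine_groups(raw_groups: dict[str, list[GeneRecord]]) -> list[OrthoGroup]:
    """Partition each raw group by exact annotation-string equality.

    Annotation strings are compared after trimming leading/trailing
    whitespace, case-sensitively. Members with a missing annotation are
    placed in their own singleton refined group (logged). Membership is
    conserved: no gene is lost or duplicated.
    """
    refined: list[OrthoGroup] = []
    for raw_id in sorted(raw_groups):
        members = raw_groups[raw_id]
        by_annotation: dict[str, list[GeneRecord]] = {}
        orphans: list[GeneRecord] = []
        for rec in members:
            ann = (rec.annotation or "").strip()
            if not ann:
                orphans.append(rec)
            else:
                by_annotation.setdefault(ann, []).append(rec)
        sub = 0
        for ann in sorted(by_annotation):
            refined.append(OrthoGroup(group_id=f"{raw_id}.{sub}", members=by_annotation[ann]))
            sub += 1
        for rec in orphans:
            logger.warning("gene %s/%s lacks an annotation; singleton group", rec.genome_id, rec.gene_id)
            refined.append(OrthoGroup(group_id=f"{raw_id}.{sub}", members=[rec]))
            sub += 1
    return refined


def presence_absence(groups: list[OrthoGroup], genome_ids: list[str]) -> pd.DataFrame:
    """Binary group x genome matrix: 1 iff the genome contributes >= 1 member."""
    data = {}
    for g in groups:
        present = g.genome_ids
        data[g.group_id] = [1 if gid in present else 0 for gid in genome_ids]
    return pd.DataFrame.from_dict(data, orient="index", columns=list(genome_ids)).sort_index()


def write_groups_tsv(groups: list[OrthoGroup], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("group_id\tgenome_id\tgene_id\tannotation\n")
        for g in sorted(groups, key=lambda g: g.group_id):
            for m in g.members:
                fh.write(f"{g.group_id}\t{m.genome_id}\t{m.gene_id}\t{m.annotation}\n")


def read_groups_tsv(path: str | Path, records: list[GeneRecord]) -> list[OrthoGroup]:
    df = pd.read_csv(path, sep="\t")
    by_key = {r.key: r for r in records}
    by_group: dict[str, list[GeneRecord]] = {}
    for row in df.itertuples(index=False):
        rec = by_key.get((row.genome_id, row.gene_id))
        if rec is not None:
            by_group.setdefault(str(row.group_id), []).append(rec)
    return [
        OrthoGroup(group_id=g, members=sorted(m, key=lambda r: r.key))
        for g, m in sorted(by_group.items())
    ]
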