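"""Synthetic pangenome generator with planted erosion.

Emulates a clade of related bacterial genomes whose gene content erodes
along a species phylogeny at pathway-specific rates, and whose retained
genes degrade into pseudogenes through explicit, recorded lesions:

* ``internal_stop``    — one sense codon replaced by TAA/TAG/TGA;
* ``frameshift``       — one indel whose length is not a multiple of 3;
* ``stop_frameshift``  — both of the above, co-planted on the same gene;
* ``gap_decay``        — a contiguous, codon-aligned deletion removing
  strictly more than 30% (and at most 60%) of the CDS.

The species tree is a pure-birth (Yule) tree whose branches receive Gamma
rate multipliers, so leaves differ in their total erosion exposure — the
genome-size gradient that the downstream pathway-erosion statistics detect.
Substitutions follow a K80-like scheme (transition:transversion 2:1) and
are nonsense-free: a substitution that would create an in-frame internal
stop, or touch the start or terminal stop codon, is reverted, so the
planted lesions are the only source of pseudogenization.

Every simulated gene is tracked in a :class:`GroundTruth` object mapping it
to its family, status and lesion mechanism, making the full downstream
pipeline testable without any external data.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .orthology import GeneRecord

logger = logging.getLogger(__name__)

MECHANISMS = ("internal_stop", "frameshift", "stop_frameshift", "gap_decay")
STOP_CODONS = ("TAA", "TAG", "TGA")

_BASE_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)
# codon code = 16*b0 + 4*b1 + b2 with A,C,G,T = 0..3
_STOP_CODES = np.array([48, 50, 56])  # TAA, TAG, TGA


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class PathwaySpec:
    """One COG functional category with its erosion parameters.

    ``loss_rate`` is the Poisson rate of whole-gene loss events per unit
    branch length; ``pseudo_rate`` the rate at which retained genes decay
    into pseudogenes per unit root-to-leaf path length.
    """

    letter: str
    loss_rate: float
    pseudo_rate: float


#: Default pathway panel: fast-eroding transcription (K), pseudogene-rich
#: replication/recombination/repair (L), eroding motility (N), and two
#: essentially preserved housekeeping categories (E, J).
DEFAULT_PATHWAYS = (
    PathwaySpec("K", 0.8, 0.3),
    PathwaySpec("L", 0.5, 0.8),
    PathwaySpec("N", 0.3, 0.4),
    PathwaySpec("E", 0.1, 0.05),
    PathwaySpec("J", 0.0, 0.02),
)

DEFAULT_MECH_PROBS = {
    "internal_stop": 0.2,
    "frameshift": 0.2,
    "stop_frameshift": 0.3,
    "gap_decay": 0.3,
}


@dataclass(frozen=True)
class SimulationConfig:
    n_taxa: int = 20
    n_families: int = 1000
    family_length_codons: int = 200
    pathways: tuple[PathwaySpec, ...] = DEFAULT_PATHWAYS
    mech_probs: dict = field(default_factory=lambda: dict(DEFAULT_MECH_PROBS))
    subst_rate: float = 0.02
    birth_rate: float = 1.0
    #: shape of the Gamma branch-rate multipliers (mean 1); None = strict clock
    rate_gamma_shape: float | None = 2.0
    spacer_range: tuple[int, int] = (50, 500)
    motility_category: str = "N"
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 3:
            raise ConfigurationError("n_taxa must be >= 3")
        if self.family_length_codons < 20:
            raise ConfigurationError("family_length_codons must be >= 20")
        if self.n_families < 1:
            raise ConfigurationError("n_families must be >= 1")
        if not self.pathways:
            raise ConfigurationError("at least one pathway is required")
        for pw in self.pathways:
            if pw.loss_rate < 0 or pw.pseudo_rate < 0:
                raise ConfigurationError("rates must be >= 0")
        unknown = set(self.mech_probs) - set(MECHANISMS)
        if unknown:
            raise ConfigurationError(f"unknown mechanisms: {sorted(unknown)}")
        total = sum(self.mech_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError("mech_probs must sum to 1")
        if any(p < 0 for p in self.mech_probs.values()):
            raise ConfigurationError("mech_probs must be >= 0")
        if self.subst_rate < 0 or self.birth_rate <= 0:
            raise ConfigurationError("invalid rate")


@dataclass
class GroundTruth:
    """Planted truth for one simulated pangenome."""

    true_tree: dendropy.Tree
    presence: pd.DataFrame  # families x genomes, bool
    true_groups: dict[str, set[tuple[str, str]]]
    status: dict[tuple[str, str], str]  # (genome, gene) -> intact | pseudogene:<mech>
    cog_map: dict[str, frozenset[str]]
    leaf_depths: dict[str, float]

    def mechanism(self, genome_id: str, gene_id: str) -> str | None:
        s = self.status[(genome_id, gene_id)]
        return s.split(":", 1)[1] if s.startswith("pseudogene:") else None


@dataclass
class SimulatedPangenome:
    config: SimulationConfig
    truth: GroundTruth
    records: list[GeneRecord]
    genomes: dict[str, str] | None  # genome -> contig sequence
    genome_meta: pd.DataFrame  # index genome_id: genome_size_bp, phenotype
    products: dict[str, str]  # family -> annotation string


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    """Independent, reproducible RNG substream per simulation stage."""
    return np.random.default_rng([config.seed, stage])


def gene_id_for(genome_id: str, family_id: str) -> str:
    return f"{genome_id}_{family_id}"


# ---------------------------------------------------------------------------
# species tree


def simulate_species_tree(config: SimulationConfig) -> dendropy.Tree:
    """Pure-birth species tree with Gamma-relaxed branch rates.

    Lineages split at total rate ``birth_rate * k``; after the last split
    one further exponential waiting time is added so every pendant branch
    is positive. Leaves are labelled G01..Gnn in preorder.
    """
    rng = _rng(config, 1)
    tree = dendropy.Tree()
    root = tree.seed_node
    active = []
    for _ in range(2):
        child = dendropy.Node()
        child.edge.length = 0.0
        root.add_child(child)
        active.append(child)
    while len(active) < config.n_taxa:
        k = len(active)
        wait = rng.exponential(1.0 / (config.birth_rate * k))
        for node in active:
            node.edge.length += wait
        idx = int(rng.integers(k))
        parent = active.pop(idx)
        for _ in range(2):
            child = dendropy.Node()
            child.edge.length = 0.0
            parent.add_child(child)
            active.append(child)
    wait = rng.exponential(1.0 / (config.birth_rate * config.n_taxa))
    for node in active:
        node.edge.length += wait

    if config.rate_gamma_shape is not None:
        shape = config.rate_gamma_shape
        for node in tree.preorder_node_iter():
            if node is root:
                continue
            node.edge.length *= rng.gamma(shape, 1.0 / shape)

    width = max(2, len(str(config.n_taxa)))
    counter = 0
    ns = tree.taxon_namespace
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            counter += 1
            taxon = ns.new_taxon(label=f"G{counter:0{width}d}")
            node.taxon = taxon
    return tree


def leaf_depths(tree: dendropy.Tree) -> dict[str, float]:
    """Root-to-leaf path lengths keyed by leaf label."""
    depths = {}
    for leaf in tree.leaf_node_iter():
        d = 0.0
        node = leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths[leaf.taxon.label] = d
    return depths


# ---------------------------------------------------------------------------
# gene content


def family_ids(config: SimulationConfig) -> list[str]:
    width = max(4, len(str(config.n_families)))
    return [f"F{i:0{width}d}" for i in range(config.n_families)]


def family_pathways(config: SimulationConfig) -> dict[str, PathwaySpec]:
    """Round-robin assignment of families to pathways (equal split)."""
    fams = family_ids(config)
    return {fam: config.pathways[i % len(config.pathways)] for i, fam in enumerate(fams)}


def evolve_gene_content(
    tree: dendropy.Tree, config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Irreversible Poisson gene loss along the tree.

    Returns a families x genomes boolean presence matrix. A family lost on
    a branch is absent from every descendant leaf; the per-branch loss
    probability for pathway rate r and branch length t is 1 - exp(-r t).
    """
    if rng is None:
        rng = _rng(config, 2)
    fams = family_ids(config)
    pw = family_pathways(config)
    rates = np.array([pw[f].loss_rate for f in fams])
    states: dict[int, np.ndarray] = {id(tree.seed_node): np.ones(len(fams), dtype=bool)}
    leaf_cols = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        p_loss = 1.0 - np.exp(-rates * (node.edge.length or 0.0))
        keep = rng.random(len(fams)) >= p_loss
        state = states[id(node.parent_node)] & keep
        states[id(node)] = state
        if node.is_leaf():
            leaf_cols[node.taxon.label] = state
    genomes = sorted(leaf_cols)
    return pd.DataFrame({g: leaf_cols[g] for g in genomes}, index=fams)


def draw_statuses(
    tree: dendropy.Tree,
    presence: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> dict[tuple[str, str], str]:
    """Draw intact/pseudogene status (with mechanism) for every emitted gene.

    A retained gene pseudogenizes with probability 1 - exp(-psi * depth).
    Two identifiability constraints apply: families present in a single
    genome are never pseudogenized, and every family keeps at least one
    intact member (the copy in the lexicographically first genome is
    reverted if the draws would degrade all members) — the alignment-based
    classification rule is comparative and needs an intact homolog.
    """
    if rng is None:
        rng = _rng(config, 3)
    depths = leaf_depths(tree)
    pw = family_pathways(config)
    mech_names = [m for m in MECHANISMS if config.mech_probs.get(m, 0.0) > 0]
    mech_p = np.array([config.mech_probs[m] for m in mech_names])
    if mech_p.size:
        mech_p = mech_p / mech_p.sum()

    status: dict[tuple[str, str], str] = {}
    genomes = list(presence.columns)
    pres = presence.to_numpy()
    fams = list(presence.index)
    n_present = pres.sum(axis=1)
    for gi, genome in enumerate(genomes):
        d = depths[genome]
        for fi, fam in enumerate(fams):
            if not pres[fi, gi]:
                continue
            gene = gene_id_for(genome, fam)
            psi = pw[fam].pseudo_rate
            p = 1.0 - np.exp(-psi * d)
            if n_present[fi] >= 2 and mech_names and rng.random() < p:
                mech = mech_names[int(rng.choice(len(mech_names), p=mech_p))]
                status[(genome, gene)] = f"pseudogene:{mech}"
            else:
                status[(genome, gene)] = "intact"
    # keep >= 1 intact member per family
    for fi, fam in enumerate(fams):
        members = [(genomes[gi], gene_id_for(genomes[gi], fam)) for gi in range(len(genomes)) if pres[fi, gi]]
        if members and all(status[m].startswith("pseudogene") for m in members):
            status[min(members)] = "intact"
    return status


# ---------------------------------------------------------------------------
# sequences


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return _BASE_LUT[rng.integers(0, 4, size=length)].tobytes().decode()


def point_mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute a ``rate`` fraction of positions (uniform random new base)."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    codes = np.zeros(arr.size, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        codes[arr == b] = i
    n_mut = int(round(rate * arr.size))
    pos = rng.choice(arr.size, size=n_mut, replace=False)
    codes[pos] = (codes[pos] + rng.integers(1, 4, size=n_mut)) % 4
    return _BASE_LUT[codes].tobytes().decode()


def translate_cds(cds: str) -> str:
    """Frame-1 translation (bacterial code); internal stops rendered as X.

    A terminal stop codon (in-frame) is stripped; a trailing partial codon
    of a frame-inconsistent CDS is ignored.
    """
    k = len(cds) // 3 * 3
    aa = str(Seq(cds[:k]).translate(table=11))
    if len(cds) % 3 == 0 and aa.endswith("*"):
        aa = aa[:-1]
    return aa.replace("*", "X")


def _ancestral_sequences(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """(n_families, L) base-code array of ancestral CDSs (ATG ... stop)."""
    n, ncod = config.n_families, config.family_length_codons
    arr = rng.integers(0, 4, size=(n, ncod * 3)).astype(np.uint8)
    arr[:, 0:3] = [0, 3, 2]  # ATG
    stops = np.array([[3, 0, 0], [3, 0, 2], [3, 2, 0]], dtype=np.uint8)
    arr[:, -3:] = stops[rng.integers(0, 3, size=n)]
    codons = arr.reshape(n, ncod, 3)
    codes = codons[:, :, 0].astype(int) * 16 + codons[:, :, 1] * 4 + codons[:, :, 2]
    bad = np.isin(codes, _STOP_CODES)
    bad[:, -1] = False
    # resample internal stop codons until none remain
    while bad.any():
        idx = np.argwhere(bad)
        codons[idx[:, 0], idx[:, 1]] = rng.integers(0, 4, size=(len(idx), 3)).astype(np.uint8)
        codes = codons[:, :, 0].astype(int) * 16 + codons[:, :, 1] * 4 + codons[:, :, 2]
        bad = np.isin(codes, _STOP_CODES)
        bad[:, -1] = False
    return arr


def _mutate_branch(parent: np.ndarray, blen: float, config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    child = parent.copy()
    p = 1.0 - np.exp(-config.subst_rate * blen)
    mask = rng.random(child.shape) < p
    mask[:, :3] = False
    mask[:, -3:] = False
    if mask.any():
        old = child[mask]
        u = rng.random(old.size)
        new = np.where(u < 2 / 3, old ^ 2, np.where(u < 2 / 3 + 1 / 6, old ^ 1, old ^ 3))
        child[mask] = new.astype(np.uint8)
        # revert substitutions creating in-frame internal stops
        n, L = child.shape
        codons = child.reshape(n, L // 3, 3)
        codes = codons[:, :, 0].astype(int) * 16 + codons[:, :, 1] * 4 + codons[:, :, 2]
        bad = np.isin(codes, _STOP_CODES)
        bad[:, -1] = False
        if bad.any():
            pcod = parent.reshape(n, L // 3, 3)
            codons[bad] = pcod[bad]
    return child


def _evolve_sequences(
    tree: dendropy.Tree, config: SimulationConfig, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Evolve all family CDSs along the tree; returns leaf label -> array."""
    ancestral = _ancestral_sequences(config, rng)
    states = {id(tree.seed_node): ancestral}
    leaves = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        child = _mutate_branch(states[id(node.parent_node)], node.edge.length or 0.0, config, rng)
        states[id(node)] = child
        if node.is_leaf():
            leaves[node.taxon.label] = child
    return leaves


def _plant_lesion(cds: str, mech: str, rng: np.random.Generator) -> str | None:
    """Apply one recorded lesion to a CDS; None if the CDS cannot host it."""
    n_codons = len(cds) // 3
    if n_codons < 6:
        return None

    def plant_stop(s: str) -> tuple[str, int]:
        # internal: strictly before the last sense codon
        idx = int(rng.integers(1, n_codons - 2))
        stop = STOP_CODONS[int(rng.integers(0, 3))]
        return s[: 3 * idx] + stop + s[3 * idx + 3 :], idx

    def plant_frameshift(s: str, lo: int = 3) -> str:
        ell = int(rng.integers(1, 3))
        pos = int(rng.integers(lo, len(s) - 3))
        ins = random_sequence(ell, rng)
        return s[:pos] + ins + s[pos:]

    if mech == "internal_stop":
        return plant_stop(cds)[0]
    if mech == "frameshift":
        return plant_frameshift(cds)
    if mech == "stop_frameshift":
        # nonsense mutation first, then an indel 3' of it: once translation
        # stops prematurely the downstream sequence is released from
        # selection, so frame-disrupting indels accumulate there
        s, idx = plant_stop(cds)
        return plant_frameshift(s, lo=3 * (idx + 1))
    if mech == "gap_decay":
        L = len(cds)
        min_codons = int(np.floor(0.30 * L)) // 3 + 1
        max_codons = int(np.floor(0.60 * L)) // 3
        if max_codons < min_codons or n_codons - 1 - min_codons < 1:
            return None
        n_del = int(rng.integers(min_codons, max_codons + 1))
        start = int(rng.integers(1, n_codons - 1 - n_del + 1))
        return cds[: 3 * start] + cds[3 * (start + n_del) :]
    raise ValueError(f"unknown mechanism {mech!r}")


_PRODUCT_POOL = [
    "hypothetical protein",
    "ABC transporter ATP-binding protein",
    "ABC transporter permease",
    "MFS transporter",
    "TonB-dependent receptor",
    "DNA polymerase III subunit",
    "DNA gyrase subunit A",
    "recombinase RecA",
    "transcriptional regulator, LysR family",
    "RNA polymerase sigma factor",
    "flagellar basal body rod protein",
    "flagellar motor switch protein",
    "pilus assembly protein",
    "chemotaxis protein CheY",
    "50S ribosomal protein",
    "30S ribosomal protein",
    "elongation factor Tu",
    "aminotransferase class I",
    "glutamine synthetase",
    "pyridoxal phosphate-dependent enzyme",
    "short-chain dehydrogenase",
    "acyl-CoA dehydrogenase",
    "cytochrome c oxidase subunit",
    "NADH-quinone oxidoreductase subunit",
    "outer membrane protein assembly factor",
    "peptidase S9 family protein",
    "glycosyltransferase family 2 protein",
    "two-component sensor histidine kinase",
    "response regulator transcription factor",
    "pyrethroid hydrolase",
]


def _family_products(config: SimulationConfig, rng: np.random.Generator) -> dict[str, str]:
    fams = family_ids(config)
    picks = rng.integers(0, len(_PRODUCT_POOL), size=len(fams))
    return {f: _PRODUCT_POOL[int(k)] for f, k in zip(fams, picks)}


# ---------------------------------------------------------------------------
# top-level simulation


def simulate_pangenome(config: SimulationConfig, with_sequences: bool = True) -> SimulatedPangenome:
    """Run the full simulation.

    With ``with_sequences=False`` only the tree, gene content, statuses and
    genome sizes are produced (sequence evolution and lesion planting are
    skipped); genome sizes then use nominal gene lengths, ignoring the
    small length changes lesions would introduce.
    """
    tree = simulate_species_tree(config)
    presence = evolve_gene_content(tree, config, _rng(config, 2))
    status = draw_statuses(tree, presence, config, _rng(config, 3))
    fams = family_ids(config)
    pw = family_pathways(config)
    cog_map = {f: frozenset({pw[f].letter}) for f in fams}
    genomes_order = list(presence.columns)

    true_groups: dict[str, set[tuple[str, str]]] = {f: set() for f in fams}
    for fi, fam in enumerate(fams):
        for genome in genomes_order:
            if presence.at[fam, genome]:
                true_groups[fam].add((genome, gene_id_for(genome, fam)))

    products = _family_products(config, _rng(config, 7))

    records: list[GeneRecord] = []
    genomes_seq: dict[str, str] | None = None
    sizes: dict[str, int] = {}

    lesion_rng = _rng(config, 5)
    spacer_rng = _rng(config, 6)
    lo, hi = config.spacer_range

    if with_sequences:
        leaf_arrays = _evolve_sequences(tree, config, _rng(config, 4))
        genomes_seq = {}
        for genome in genomes_order:
            arr = leaf_arrays[genome]
            parts = [random_sequence(int(spacer_rng.integers(lo, hi + 1)), spacer_rng)]
            for fi, fam in enumerate(fams):
                if not presence.at[fam, genome]:
                    continue
                gene = gene_id_for(genome, fam)
                cds = _BASE_LUT[arr[fi]].tobytes().decode()
                mech = None
                if status[(genome, gene)].startswith("pseudogene:"):
                    mech = status[(genome, gene)].split(":", 1)[1]
                    mutated = _plant_lesion(cds, mech, lesion_rng)
                    if mutated is None:
                        logger.warning("family %s too short for %s; left intact", fam, mech)
                        status[(genome, gene)] = "intact"
                    else:
                        cds = mutated
                records.append(
                    GeneRecord(
                        genome_id=genome,
                        gene_id=gene,
                        annotation=products[fam],
                        nt_seq=cds,
                        aa_seq=translate_cds(cds),
                    )
                )
                parts.append(cds)
                parts.append(random_sequence(int(spacer_rng.integers(lo, hi + 1)), spacer_rng))
            contig = "".join(parts)
            genomes_seq[genome] = contig
            sizes[genome] = len(contig)
    else:
        gene_len = 3 * config.family_length_codons
        for genome in genomes_order:
            size = int(spacer_rng.integers(lo, hi + 1))
            for fam in fams:
                if presence.at[fam, genome]:
                    size += gene_len + int(spacer_rng.integers(lo, hi + 1))
            sizes[genome] = size

    phenotype = _phenotypes(presence, cog_map, config)
    meta = pd.DataFrame(
        {"genome_size_bp": [sizes[g] for g in genomes_order], "phenotype": [phenotype[g] for g in genomes_order]},
        index=pd.Index(genomes_order, name="genome_id"),
    )
    truth = GroundTruth(
        true_tree=tree,
        presence=presence,
        true_groups=true_groups,
        status=status,
        cog_map=cog_map,
        leaf_depths=leaf_depths(tree),
    )
    return SimulatedPangenome(
        config=config,
        truth=truth,
        records=records,
        genomes=genomes_seq,
        genome_meta=meta,
        products=products,
    )


def _phenotypes(presence: pd.DataFrame, cog_map: dict[str, frozenset[str]], config: SimulationConfig) -> dict[str, str]:
    """Motility phenotype: motile iff >= 50% of motility-category families retained."""
    motility_fams = [f for f, cats in cog_map.items() if config.motility_category in cats]
    out = {}
    for genome in presence.columns:
        if not motility_fams:
            out[genome] = "unknown"
            continue
        frac = presence.loc[motility_fams, genome].mean()
        out[genome] = "motile" if frac >= 0.5 else "immobile"
    return out


# ---------------------------------------------------------------------------
# emission / loading


def emit(sim: SimulatedPangenome, outdir: str | Path) -> None:
    """Write the simulated pangenome to standard flat files.

    Layout: assemblies/*.fna, cds/*.ffn, proteins/*.faa,
    annotations/*.gff3, metadata.tsv, cog_map.tsv, tree.nwk,
    truth/families.tsv, truth/status.tsv.
    """
    if sim.genomes is None:
        raise ValueError("simulation was run without sequences; nothing to emit")
    outdir = Path(outdir)
    for sub in ("assemblies", "cds", "proteins", "annotations", "truth"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)

    by_genome: dict[str, list[GeneRecord]] = {}
    for rec in sim.records:
        by_genome.setdefault(rec.genome_id, []).append(rec)

    for genome, contig in sim.genomes.items():
        contig_id = f"{genome}_contig1"
        SeqIO.write(
            [SeqRecord(Seq(contig), id=contig_id, description="")],
            outdir / "assemblies" / f"{genome}.fna",
            "fasta",
        )
        recs = by_genome.get(genome, [])
        SeqIO.write(
            [SeqRecord(Seq(r.nt_seq), id=r.gene_id, description=r.annotation) for r in recs],
            outdir / "cds" / f"{genome}.ffn",
            "fasta",
        )
        SeqIO.write(
            [SeqRecord(Seq(r.aa_seq), id=r.gene_id, description=r.annotation) for r in recs],
            outdir / "proteins" / f"{genome}.faa",
            "fasta",
        )
        with open(outdir / "annotations" / f"{genome}.gff3", "w") as fh:
            fh.write("##gff-version 3\n")
            fh.write(f"##sequence-region {contig_id} 1 {len(contig)}\n")
            cursor = 0
            for r in recs:
                start = contig.index(r.nt_seq, cursor)  # genes are laid out in order
                end = start + len(r.nt_seq)  # half-open
                cursor = end
                fh.write(
                    f"{contig_id}\tpanerosion\tCDS\t{start + 1}\t{end}\t.\t+\t0\t"
                    f"ID={r.gene_id};product={r.annotation}\n"
                )

    sim.genome_meta.to_csv(outdir / "metadata.tsv", sep="\t")

    with open(outdir / "cog_map.tsv", "w") as fh:
        fh.write("gene_id\tcategories\n")
        for rec in sim.records:
            fam = rec.gene_id.split("_", 1)[1]
            cats = "".join(sorted(sim.truth.cog_map[fam]))
            fh.write(f"{rec.gene_id}\t{cats}\n")

    with open(outdir / "tree.nwk", "w") as fh:
        fh.write(sim.truth.true_tree.as_string(schema="newick"))

    with open(outdir / "truth" / "families.tsv", "w") as fh:
        fh.write("family_id\tgenome_id\tgene_id\n")
        for fam in sorted(sim.truth.true_groups):
            for genome, gene in sorted(sim.truth.true_groups[fam]):
                fh.write(f"{fam}\t{genome}\t{gene}\n")

    with open(outdir / "truth" / "status.tsv", "w") as fh:
        fh.write("genome_id\tgene_id\tstatus\tmechanism\n")
        for (genome, gene), st in sorted(sim.truth.status.items()):
            base, _, mech = st.partition(":")
            fh.write(f"{genome}\t{gene}\t{base}\t{mech}\n")


def load_records(outdir: str | Path) -> list[GeneRecord]:
    """Re-read emitted CDS + protein FASTA into GeneRecords."""
    outdir = Path(outdir)
    records = []
    for ffn in sorted((outdir / "cds").glob("*.ffn")):
        genome = ffn.stem
        proteins = {
            r.id: str(r.seq) for r in SeqIO.parse(outdir / "proteins" / f"{genome}.faa", "fasta")
        }
        for rec in SeqIO.parse(ffn, "fasta"):
            annotation = rec.description.split(None, 1)[1] if " " in rec.description else ""
            records.append(
                GeneRecord(
                    genome_id=genome,
                    gene_id=rec.id,
                    annotation=annotation,
                    nt_seq=str(rec.seq),
                    aa_seq=proteins[rec.id],
                )
            )
    return records


def load_truth_groups(outdir: str | Path) -> dict[str, set[tuple[str, str]]]:
    df = pd.read_csv(Path(outdir) / "truth" / "families.tsv", sep="\t")
    groups: dict[str, set[tuple[str, str]]] = {}
    for row in df.itertuples(index=False):
        groups.setdefault(row.family_id, set()).add((row.genome_id, row.gene_id))
    return groups


def load_truth_status(outdir: str | Path) -> dict[tuple[str, str], str]:
    df = pd.read_csv(Path(outdir) / "truth" / "status.tsv", sep="\t", keep_default_na=False)
    out = {}
    for row in df.itertuples(index=False):
        st = row.status if not row.mechanism else f"{row.status}:{row.mechanism}"
        out[(row.genome_id, row.gene_id)] = st
    return out
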