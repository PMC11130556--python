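"""Synthetic barcode datasets with known truth.

The generator emulates the statistical structure the downstream analysis
assumes: a handful of species separated by a clear barcode gap, modest
within-species variation, occasional IUPAC ambiguity codes, and optionally a
clade-restricted in-frame deletion represented as shared gap columns.

Sites evolve i.i.d. under Jukes–Cantor along an ultrametric species tree;
within each species, individuals radiate star-like from the species ancestor
(no coalescent structure — enough to realise the intra/inter divergence gap
that threshold delimitation relies on).  Branch lengths are calibrated
through the closed-form JC map between expected substitutions per site and
expected p-distance, so the configured divergences are what the simulated
distance matrix converges to.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .seqio import Alignment, BarcodeRecord, write_alignment, write_labels

_BASES = np.array(list("ACGT"), dtype="U1")
# two-base ambiguity code covering {true base, alternative}
_PAIR_CODE = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}


@dataclass
class DeletionSpec:
    """A clade-restricted deletion: applied to every record of the listed
    species, shown as gap columns at ``position`` (1-based)."""

    clade: list[str]
    length: int = 6
    position: int = 476


@dataclass
class SimConfig:
    """Generator settings.

    Defaults mirror a typical well-separated barcoding study: seven species,
    full-length 658 bp marker, ~1% expected within-species and ~8% expected
    between-species p-distance, and a low rate of ambiguity codes standing in
    for heterozygous-like miscalls.
    """

    n_species: int = 7
    n_per_species: int | list[int] = 5
    seq_length: int = 658
    intra_divergence: float = 0.01
    inter_divergence: float = 0.08
    ambiguity_rate: float = 0.001
    deletion: DeletionSpec | None = None
    seed: int = 0

    def per_species_counts(self) -> list[int]:
        if isinstance(self.n_per_species, int):
            return [self.n_per_species] * self.n_species
        if len(self.n_per_species) != self.n_species:
            raise ValueError("per-species counts do not match n_species")
        return list(self.n_per_species)

    def validate(self) -> None:
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if any(c < 1 for c in self.per_species_counts()):
            raise ValueError("every species needs at least 1 record")
        if not self.intra_divergence < self.inter_divergence:
            raise ValueError(
                "intra_divergence must be below inter_divergence: "
                "without a barcode gap there is nothing to recover"
            )
        if self.deletion is not None:
            d = self.deletion
            if d.length >= self.seq_length:
                raise ValueError("deletion longer than the sequence")
            if d.position + d.length - 1 > self.seq_length:
                raise ValueError("deletion extends past the sequence end")
        for p in (self.intra_divergence, self.inter_divergence):
            if not 0 <= p < 0.75:
                raise ValueError("expected p-distances must lie in [0, 0.75)")


@dataclass
class TruthTable:
    """Ground truth for one simulated dataset."""

    labels: dict[str, str]
    tree_newick: str
    indels: list[DeletionSpec] = field(default_factory=list)


def jc_expected_distance(branch_length: float) -> float:
    """Expected p-distance after ``branch_length`` substitutions/site under JC:
    p = (3/4)(1 - exp(-(4/3) b))."""
    if branch_length < 0:
        raise ValueError("branch length must be non-negative")
    return 0.75 * (1.0 - math.exp(-4.0 * branch_length / 3.0))


def jc_branch_length(p: float) -> float:
    """Inverse of :func:`jc_expected_distance` (p must be below 3/4)."""
    if not 0 <= p < 0.75:
        raise ValueError("p-distance must lie in [0, 0.75)")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def simulate_species_tree(cfg: SimConfig, seed: int | None = None) -> dendropy.Tree:
    """Random ultrametric species tree calibrated to the configured divergence.

    Topology by random sequential splitting.  Internal split heights are
    confined to the upper half of the root height, so every leaf-pair path
    stays within a factor of two of the deepest one; the whole tree is then
    scaled so the mean leaf-pair path equals the JC branch length whose
    expected p-distance is ``cfg.inter_divergence``.  Keeping the pairwise
    divergences in a narrow band preserves the barcode gap for every species
    pair, not just on average.  Deterministic for a given seed.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    taxa = [f"sp{i+1}" for i in range(cfg.n_species)]
    ns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.Tree(taxon_namespace=ns)

    def build(names: list[str], height: float) -> dendropy.Node:
        """Subtree over ``names`` whose root sits ``height`` above the leaves."""
        node = dendropy.Node()
        if len(names) == 1:
            node.taxon = ns.get_taxon(names[0])
            return node
        split = int(rng.integers(1, len(names)))
        for part in (names[:split], names[split:]):
            child_height = (
                float(rng.uniform(0.5, height)) if len(part) > 1 else 0.0
            )
            child = build(part, child_height)
            child.edge.length = height - child_height
            node.add_child(child)
        return node

    root = build(taxa, height=1.0)
    root.edge.length = 0.0
    tree.seed_node = root
    # rescale so mean pairwise path length hits the JC target
    pdm = tree.phylogenetic_distance_matrix()
    taxa_list = list(ns)
    pairs = [
        pdm.distance(t1, t2)
        for i, t1 in enumerate(taxa_list)
        for t2 in taxa_list[i + 1 :]
    ]
    target = jc_branch_length(cfg.inter_divergence)
    scale = target / float(np.mean(pairs))
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    return tree


def _evolve(parent: np.ndarray, branch: float, rng: np.random.Generator) -> np.ndarray:
    """One JC step: each site substitutes to a uniformly random *different*
    base with total probability (3/4)(1 - exp(-4b/3))."""
    p_change = jc_expected_distance(branch)
    child = parent.copy()
    hit = rng.random(len(parent)) < p_change
    if hit.any():
        idx = np.flatnonzero(hit)
        cur = np.searchsorted(_BASES, parent[idx])
        shift = rng.integers(1, 4, size=len(idx))
        child[idx] = _BASES[(cur + shift) % 4]
    return child


def simulate_alignment(
    cfg: SimConfig, seed: int | None = None
) -> tuple[Alignment, TruthTable]:
    """Generate a labelled alignment plus its ground truth.

    Species ancestral sequences evolve down the simulated tree; each record
    then evolves from its species ancestor on a terminal branch of half the
    intraspecific JC depth, so two conspecific records are separated by the
    full intraspecific expected divergence.  Ambiguity codes replace the true
    base with a two-base IUPAC code containing it at ``ambiguity_rate`` per
    record site.  A configured deletion blanks the window to gap characters
    in every record of the clade.
    """
    cfg.validate()
    base_seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(base_seed)
    tree = simulate_species_tree(cfg, seed=base_seed)

    root_seq = _BASES[rng.integers(0, 4, size=cfg.seq_length)]
    species_seq: dict[str, np.ndarray] = {}

    def descend(node: dendropy.Node, seq: np.ndarray) -> None:
        for child in node.child_nodes():
            child_seq = _evolve(seq, child.edge.length or 0.0, rng)
            if child.is_leaf():
                species_seq[child.taxon.label] = child_seq
            else:
                descend(child, child_seq)

    if tree.seed_node.is_leaf():  # n_species == 1 is rejected by validate()
        raise AssertionError
    descend(tree.seed_node, root_seq)

    tip_branch = jc_branch_length(cfg.intra_divergence) / 2.0
    counts = cfg.per_species_counts()
    records: list[BarcodeRecord] = []
    labels: dict[str, str] = {}
    for sp, n in zip(sorted(species_seq), counts):
        for k in range(n):
            seq = _evolve(species_seq[sp], tip_branch, rng)
            # heterozygous-like ambiguity injection
            amb = rng.random(cfg.seq_length) < cfg.ambiguity_rate
            chars = seq.copy()
            for i in np.flatnonzero(amb):
                alt = _BASES[(np.searchsorted(_BASES, seq[i]) + rng.integers(1, 4)) % 4]
                chars[i] = _PAIR_CODE[frozenset((str(seq[i]), str(alt)))]
            rid = f"{sp}_rec{k+1}"
            if cfg.deletion is not None and sp in cfg.deletion.clade:
                lo = cfg.deletion.position - 1
                chars[lo : lo + cfg.deletion.length] = "-"
            records.append(BarcodeRecord(rid, "".join(chars), species=sp))
            labels[rid] = sp
    truth = TruthTable(
        labels=labels,
        tree_newick=tree.as_string(schema="newick").strip(),
        indels=[cfg.deletion] if cfg.deletion else [],
    )
    return Alignment(records), truth


def write_dataset(
    aln: Alignment, truth: TruthTable, outdir: str | Path, prefix: str = "sim"
) -> dict[str, Path]:
    """Write FASTA + labels TSV + truth TSV + newick tree; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / f"{prefix}.fasta",
        "labels": outdir / f"{prefix}_labels.tsv",
        "truth": outdir / f"{prefix}_truth.tsv",
        "tree": outdir / f"{prefix}_tree.nwk",
    }
    write_alignment(aln, paths["fasta"])
    write_labels(truth.labels, paths["labels"])
    with open(paths["truth"], "w") as fh:
        fh.write("# record_id\ttrue_species\n")
        for rid, sp in truth.labels.items():
            fh.write(f"{rid}\t{sp}\n")
        for d in truth.indels:
            fh.write(f"# indel\tclade={','.join(d.clade)}\tlength={d.length}\tposition={d.position}\n")
    with open(paths["tree"], "w") as fh:
        fh.write(truth.tree_newick + "\n")
    return paths
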