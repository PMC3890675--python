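"""Synthetic multi-marker barcode datasets with controlled divergence.

The generator emulates the structure of a family-scale plant barcoding
study: a few dozen species with one to six accessions each, several
markers of different lengths and substitution rates, hierarchical
taxonomy (genus / subgenus / section) and per-marker specimen dropout.

Model
-----
A pure-birth (Yule) species tree is grown to ``n_species`` tips and made
ultrametric at height ``interspecific_depth`` (expected substitutions
per site from root to tip at relative rate 1).  Because recognised
species are differentiated lineages rather than instantaneous splits, a
terminal no-speciation period equal to ``min_split_frac`` of the final
height is appended before rescaling, which bounds every split away from
the present.  Within each species, accessions attach to the species tip
as a star, each on a branch drawn exponentially with mean
``intraspecific_depth / 2``, so the expected divergence between two
conspecific accessions is ``intraspecific_depth`` while its
distribution keeps the heavy right tail that within-species coalescent
variation produces.  Sequences then evolve down the tree under the
Kimura two-parameter process (uniform base frequencies, transition rate
alpha and total transversion rate 2*beta with alpha/(2*beta) = kappa and
alpha + 2*beta = 1 per unit branch length), independently per site and
per marker, with branch lengths multiplied by the marker's relative
rate.  Finally each (specimen, marker) pair is dropped with the
marker's dropout probability, mimicking unequal PCR success.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .distances import DistanceMatrix
from .io_alignments import (
    MarkerAlignment,
    SpecimenRecord,
    write_fasta_alignment,
    write_metadata,
)
from .trees import Node, Tree

_BASES = np.array(list("ACGT"))
#: transition partner of A,C,G,T
_TS_PARTNER = np.array([2, 3, 0, 1], dtype=np.uint8)
#: the two transversion partners of A,C,G,T
_TV_ONE = np.array([1, 0, 1, 0], dtype=np.uint8)
_TV_TWO = np.array([3, 2, 3, 2], dtype=np.uint8)


@dataclass(frozen=True)
class MarkerModel:
    """Evolutionary model of one simulated marker."""

    name: str
    length: int
    relative_rate: float = 1.0
    kappa: float = 2.0
    dropout_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"marker {self.name!r}: non-positive length")
        if self.kappa < 0:
            raise ValueError(f"marker {self.name!r}: kappa must be >= 0")
        if not 0.0 <= self.dropout_prob < 1.0:
            raise ValueError(f"marker {self.name!r}: dropout_prob must be in [0, 1)")


#: defaults emulating a four-marker plastid/nuclear panel: lengths match
#: typical aligned widths and relative rates reproduce the observed
#: ordering rbcLa < matK < trnH-psbA < nrITS of between-species divergence;
#: dropout rates mirror the markers' unequal sequencing success
STUDY_MARKERS = (
    MarkerModel("rbcLa", 552, relative_rate=0.12, kappa=2.0, dropout_prob=0.10),
    MarkerModel("matK", 771, relative_rate=0.19, kappa=2.0, dropout_prob=0.20),
    MarkerModel("trnH-psbA", 1034, relative_rate=0.63, kappa=2.0, dropout_prob=0.30),
    MarkerModel("nrITS", 821, relative_rate=1.47, kappa=2.0, dropout_prob=0.45),
)


@dataclass(frozen=True)
class TaxonomyShape:
    """How many higher taxa to carve out of the species tree."""

    n_genera: int = 6
    n_subgenera: int = 2
    n_sections: int = 5


@dataclass(frozen=True)
class SimParams:
    """Full specification of one synthetic dataset."""

    n_species: int = 58
    accessions: tuple[int, int] = (1, 6)
    markers: tuple[MarkerModel, ...] = STUDY_MARKERS
    interspecific_depth: float = 0.05
    intraspecific_depth: float = 0.002
    taxonomy_shape: TaxonomyShape = field(default_factory=TaxonomyShape)
    min_split_frac: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if self.interspecific_depth <= 0:
            raise ValueError("interspecific_depth must be > 0")
        if self.intraspecific_depth < 0:
            raise ValueError("intraspecific_depth must be >= 0")
        if not 0 < self.accessions[0] <= self.accessions[1]:
            raise ValueError("accessions range must satisfy 1 <= min <= max")
        if not 0.0 <= self.min_split_frac < 1.0:
            raise ValueError("min_split_frac must be in [0, 1)")
        if not self.markers:
            raise ValueError("at least one marker is required")

    def to_dict(self) -> dict:
        return {
            "n_species": self.n_species,
            "accessions": list(self.accessions),
            "markers": [
                {
                    "name": m.name,
                    "length": m.length,
                    "relative_rate": m.relative_rate,
                    "kappa": m.kappa,
                    "dropout_prob": m.dropout_prob,
                }
                for m in self.markers
            ],
            "interspecific_depth": self.interspecific_depth,
            "intraspecific_depth": self.intraspecific_depth,
            "taxonomy_shape": {
                "n_genera": self.taxonomy_shape.n_genera,
                "n_subgenera": self.taxonomy_shape.n_subgenera,
                "n_sections": self.taxonomy_shape.n_sections,
            },
            "min_split_frac": self.min_split_frac,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class SimResult:
    """Everything the generator knows about one synthetic dataset."""

    params: SimParams
    alignments: dict[str, MarkerAlignment]
    specimens: tuple[SpecimenRecord, ...]
    species_tree: Tree
    #: expected substitutions/site between species tips at relative rate 1
    species_divergence: DistanceMatrix

    def write(self, outdir: str | Path) -> None:
        """Write FASTA per marker, metadata CSV, Newick tree, provenance JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, aln in self.alignments.items():
            write_fasta_alignment(aln, outdir / f"{name}.fasta")
        write_metadata(self.specimens, outdir / "metadata.csv")
        self.species_tree.write_newick(outdir / "species_tree.nwk")
        with open(outdir / "provenance.json", "w") as fh:
            json.dump(self.params.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def simulate_species_tree(
    n_species: int,
    depth: float,
    seed: int | np.random.Generator,
    min_split_frac: float = 0.2,
) -> Tree:
    """Grow a Yule tree and rescale it ultrametric at ``depth``.

    After the tree reaches ``n_species`` lineages, a terminal period
    without speciation equal to ``min_split_frac`` of the final height
    is appended, so the most recent split sits at least that fraction of
    the height away from the tips.  Same seed, same Newick string.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    if depth <= 0:
        raise ValueError("depth must be > 0")
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    root = Node()
    birth: dict[int, float] = {}
    active: list[Node] = []
    for _ in range(2):
        child = root.add_child(Node())
        birth[id(child)] = 0.0
        active.append(child)
    t = 0.0
    while len(active) < n_species:
        t += rng.exponential(1.0 / len(active))
        idx = int(rng.integers(len(active)))
        parent = active.pop(idx)
        parent_t = t
        for _ in range(2):
            child = parent.add_child(Node())
            birth[id(child)] = parent_t
            active.append(child)
        parent.length = parent_t - birth[id(parent)]
    # terminal no-speciation period, then rescale to the requested height
    span = t if t > 0 else 1.0
    t_end = span / (1.0 - min_split_frac) if min_split_frac > 0 else span
    if t == 0.0:  # n_species == 2: two tips straight from the root
        t_end = 1.0
    for i, tip in enumerate(active):
        tip.length = t_end - birth[id(tip)]
    scale = depth / t_end
    tree = Tree(root)
    for node in tree.preorder():
        if node is not root:
            node.length *= scale
    for i, tip in enumerate(tree.leaves()):
        tip.name = f"sp{i + 1:03d}"
    return tree


def _k2p_step_probs(branch: float, kappa: float) -> tuple[float, float]:
    """(P_transition, P_each_transversion) after a branch of expected
    ``branch`` substitutions/site under K2P with ts/tv ratio ``kappa``."""
    # normalise rates so alpha + 2*beta = 1 per unit branch length,
    # with kappa = alpha / (2*beta)
    alpha = kappa / (kappa + 1.0)
    beta = 1.0 / (2.0 * (kappa + 1.0))
    t = branch
    e1 = np.exp(-4.0 * beta * t)
    e2 = np.exp(-2.0 * (alpha + beta) * t)
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv_each = 0.25 - 0.25 * e1
    return float(p_ts), float(p_tv_each)


def evolve_sequences(
    tree: Tree,
    length: int,
    kappa: float,
    rate: float,
    seed: int | np.random.Generator,
) -> dict[str, str]:
    """Evolve sequences down ``tree`` under the K2P process.

    The root sequence is uniform over {A,C,G,T}; each branch applies the
    K2P transition-probability matrix for ``branch_length * rate``
    expected substitutions per site, independently per site.  Returns a
    map from tip name to sequence string.
    """
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    states: dict[int, np.ndarray] = {
        id(tree.root): rng.integers(0, 4, size=length, dtype=np.uint8)
    }
    out: dict[str, str] = {}
    for node in tree.preorder():
        parent_state = states[id(node)]
        for child in node.children:
            p_ts, p_tv = _k2p_step_probs(child.length * rate, kappa)
            u = rng.random(length)
            pick_tv = rng.random(length) < 0.5
            s = parent_state
            child_state = s.copy()
            ts_mask = (u >= 1.0 - p_ts - 2 * p_tv) & (u < 1.0 - 2 * p_tv)
            tv_mask = u >= 1.0 - 2 * p_tv
            child_state[ts_mask] = _TS_PARTNER[s[ts_mask]]
            tv1 = tv_mask & pick_tv
            tv2 = tv_mask & ~pick_tv
            child_state[tv1] = _TV_ONE[s[tv1]]
            child_state[tv2] = _TV_TWO[s[tv2]]
            states[id(child)] = child_state
        if node.is_leaf:
            out[node.name] = "".join(_BASES[states[id(node)]])
    return out


def _partition_clades(tree: Tree, k: int) -> list[list[str]]:
    """Split the tips into ``k`` monophyletic blocks by opening the
    largest clade first (deterministic)."""
    below: dict[int, list[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = [node.name]
        else:
            below[id(node)] = sum((below[id(c)] for c in node.children), [])
    if k <= 1:
        return [below[id(tree.root)]]
    blocks: list[Node] = list(tree.root.children)
    while len(blocks) < k:
        internal = [b for b in blocks if not b.is_leaf]
        if not internal:
            break
        biggest = max(internal, key=lambda b: (len(below[id(b)]), below[id(b)][0]))
        blocks.remove(biggest)
        blocks.extend(biggest.children)
    blocks.sort(key=lambda b: below[id(b)][0])
    return [below[id(b)] for b in blocks]


def _assign_taxonomy(
    tree: Tree, shape: TaxonomyShape
) -> dict[str, tuple[str, Optional[str], Optional[str]]]:
    """Assign (genus, subgenus, section) labels to monophyletic blocks.

    Subgenera are carved out of the largest genus; sections are carved
    out of each subgenus.  Species outside the subdivided genus carry no
    subgenus/section.
    """
    genera = _partition_clades(tree, shape.n_genera)
    out: dict[str, tuple[str, Optional[str], Optional[str]]] = {}
    for gi, block in enumerate(genera):
        gname = f"Genus{gi + 1:02d}"
        for sp in block:
            out[sp] = (gname, None, None)
    # subdivide the most species-rich genus
    big_idx = max(range(len(genera)), key=lambda i: len(genera[i]))
    big_gname = f"Genus{big_idx + 1:02d}"
    big_species = set(genera[big_idx])
    subtree_blocks = _subdivide(tree, big_species, shape.n_subgenera)
    n_sections = shape.n_sections
    per_sub = max(1, n_sections // max(1, len(subtree_blocks)))
    for si, sub_block in enumerate(subtree_blocks):
        sub_name = f"Subgenus{si + 1}"
        sections = _subdivide(tree, set(sub_block), per_sub)
        for ci, sec_block in enumerate(sections):
            sec_name = f"Section{si + 1}{chr(ord('a') + ci)}"
            for sp in sec_block:
                out[sp] = (big_gname, sub_name, sec_name)
    return out


def _subdivide(tree: Tree, species: set, k: int) -> list[list[str]]:
    """Partition ``species`` into <= k blocks following tree structure."""
    below: dict[int, list[str]] = {}
    n_tips: dict[int, int] = {}
    roots: list[Node] = []
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = [node.name] if node.name in species else []
            n_tips[id(node)] = 1
        else:
            below[id(node)] = sum((below[id(c)] for c in node.children), [])
        n_tips[id(node)] = 1 if node.is_leaf else sum(
            n_tips[id(c)] for c in node.children
        )

    # maximal clades whose full tip set lies inside the species set
    def collect(node: Node) -> None:
        names = below[id(node)]
        if names and len(names) == n_tips[id(node)]:
            roots.append(node)
            return
        for c in node.children:
            collect(c)

    collect(tree.root)
    blocks = roots
    while len(blocks) < k:
        internal = [b for b in blocks if not b.is_leaf and len(below[id(b)]) > 1]
        if not internal:
            break
        biggest = max(internal, key=lambda b: (len(below[id(b)]), below[id(b)][0]))
        blocks.remove(biggest)
        blocks.extend(c for c in biggest.children if below[id(c)])
    blocks.sort(key=lambda b: below[id(b)][0])
    return [below[id(b)] for b in blocks]


def simulate_dataset(params: SimParams) -> SimResult:
    """Simulate a full multi-marker dataset under ``params``.

    Deterministic given the seed: identical parameters yield
    bit-identical sequences, metadata and trees.
    """
    rng = np.random.default_rng(params.seed)
    species_tree = simulate_species_tree(
        params.n_species,
        params.interspecific_depth,
        rng,
        min_split_frac=params.min_split_frac,
    )
    species_names = species_tree.leaf_names()
    taxonomy = _assign_taxonomy(species_tree, params.taxonomy_shape)

    # attach accessions as a star below each species tip; exponential
    # branches with mean intraspecific_depth/2 give expected pairwise
    # conspecific divergence intraspecific_depth
    lo, hi = params.accessions
    specimen_tree_root = _copy_tree(species_tree.root)
    specimen_tree = Tree(specimen_tree_root)
    specimens: list[SpecimenRecord] = []
    half_intra = params.intraspecific_depth / 2.0
    for tip in specimen_tree.leaves():
        sp = tip.name
        n_acc = int(rng.integers(lo, hi + 1))
        genus, subgenus, section = taxonomy[sp]
        tip.name = None
        for a in range(1, n_acc + 1):
            branch = float(rng.exponential(half_intra)) if half_intra > 0 else 0.0
            leaf = tip.add_child(Node(name=f"{sp}a{a}", length=branch))
            specimens.append(
                SpecimenRecord(
                    specimen_id=leaf.name,
                    species=f"{genus} {sp}",
                    genus=genus,
                    subgenus=subgenus,
                    section=section,
                )
            )

    alignments: dict[str, MarkerAlignment] = {}
    for marker in params.markers:
        tip_seqs = evolve_sequences(
            specimen_tree, marker.length, marker.kappa, marker.relative_rate, rng
        )
        if marker.dropout_prob > 0.0:
            keep = {
                sid
                for sid in tip_seqs
                if rng.random() >= marker.dropout_prob
            }
        else:
            keep = set(tip_seqs)
        kept = {s.specimen_id: tip_seqs[s.specimen_id] for s in specimens if s.specimen_id in keep}
        kept_species = {s.species for s in specimens if s.specimen_id in kept}
        if len(kept_species) < 2:
            raise ValueError(
                f"marker {marker.name!r}: dropout left fewer than 2 species"
            )
        alignments[marker.name] = MarkerAlignment(
            marker_name=marker.name, sequences=kept, length=marker.length
        )

    divergence = species_tree.path_length_matrix(order=species_names)
    return SimResult(
        params=params,
        alignments=alignments,
        specimens=tuple(specimens),
        species_tree=species_tree,
        species_divergence=divergence,
    )


def _copy_tree(node: Node) -> Node:
    clone = Node(name=node.name, length=node.length)
    for child in node.children:
        clone.add_child(_copy_tree(child))
    return clone
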