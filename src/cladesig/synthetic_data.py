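"""Synthetic proteome sets with known phylogeny and planted signatures.

The generator emulates the structure of a clade-marker study: a set of
genomes related by a known tree, split into a focal (ingroup) clade and
an outgroup; shared protein families evolved along the tree by a
uniform-replacement substitution process; clade-specific indels of
1-20 residues planted in conserved regions on the ingroup stem;
clade-restricted genes (CSPs) present only in the ingroup; and
unrelated noise proteins.  The manifest records every planted event so
recovery by the pipeline can be scored exactly.

By default the +/-20 residues flanking a planted indel are locked to
the family's ancestral sequence in every genome, which guarantees the
event satisfies the default conserved-flank rule; ``hard_mode``
disables the locking to measure sensitivity under undisturbed
substitution noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from ._align import ALPHABET, N_AA
from .csi_detect import CsiParams, find_csi_candidates
from .msa_pipeline import Msa
from .sequence_io import GroupAssignment, ProteomeSet, SequenceRecord


@dataclass
class SimConfig:
    """Study-condition parameters of the generator.

    Branch lengths are in expected substitutions per site per unit
    rate; with the defaults the typical within-family leaf-to-leaf
    identity stays around 75-90%, comfortably above the clustering
    thresholds, while still accumulating visible divergence.
    """

    n_ingroup: int = 12
    n_outgroup: int = 8
    n_families: int = 100
    family_length: int = 300
    substitution_rate: float = 1.0     # substitutions/site per unit length
    branch_length_mean: float = 0.03
    stem_length: float = 0.12          # ingroup and outgroup stems
    n_csi: int = 15
    csi_sizes: list[int] | None = None
    n_csp: int = 5
    csp_length: int = 240
    n_noise_proteins: int = 3          # per genome
    noise_length_range: tuple[int, int] = (80, 400)
    n_patchy_families: int = 0         # families randomly absent from ~30%
    hard_mode: bool = False
    seed: int = 7

    def resolved_csi_sizes(self) -> list[int]:
        if self.csi_sizes is not None:
            sizes = list(self.csi_sizes)
        elif self.n_csi == 0:
            sizes = []
        else:
            sizes = [1 + (i % 7) for i in range(self.n_csi - 1)] + [20]
        if len(sizes) != self.n_csi:
            raise ValueError(
                f"csi_sizes has {len(sizes)} entries for n_csi={self.n_csi}")
        return sizes

    def validate(self) -> None:
        if self.n_ingroup < 2 or self.n_outgroup < 2:
            raise ValueError("need >= 2 ingroup and >= 2 outgroup genomes")
        if self.n_csi > self.n_families:
            raise ValueError("more CSI events than families")
        if self.family_length < 50:
            raise ValueError("family_length must be >= 50")
        sizes = self.resolved_csi_sizes()
        for s in sizes:
            if s < 1:
                raise ValueError(f"invalid CSI size {s}")
            if self.family_length < 2 * _FLANK_LOCK + s + 20:
                raise ValueError(
                    f"family_length {self.family_length} too short for a "
                    f"size-{s} event with conserved flanks")


@dataclass(frozen=True)
class CsiEvent:
    family_id: str
    clade: str
    event_type: str  # "insertion" or "deletion"
    size: int
    position: int    # 1-based offset in the ancestral family sequence
    leaves: tuple[str, ...]


@dataclass(frozen=True)
class CspEvent:
    gene_id: str
    clade: str
    member_ids: tuple[str, ...]


@dataclass
class SimManifest:
    true_tree: str                      # newick
    families: dict[str, dict[str, str]]  # family -> genome -> seq id
    csi_events: list[CsiEvent] = field(default_factory=list)
    csp_events: list[CspEvent] = field(default_factory=list)
    noise_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "true_tree": self.true_tree,
            "families": self.families,
            "csi_events": [vars(e) | {"leaves": list(e.leaves)}
                           for e in self.csi_events],
            "csp_events": [vars(e) | {"member_ids": list(e.member_ids)}
                           for e in self.csp_events],
            "noise_ids": self.noise_ids,
        }


_FLANK_LOCK = 20


def simulate_tree(n_leaves: int, seed, mean_branch_length: float = 0.03,
                  prefix: str = "T") -> dendropy.Tree:
    """Random Yule topology with exponential branch lengths.

    Grown by repeated random leaf splitting; returned unrooted (the
    basal bifurcation is collapsed), so an n-leaf tree has 2n-3 edges.
    Deterministic given the seed (an int or a numpy Generator).
    """
    if n_leaves < 3:
        raise ValueError("need at least 3 leaves")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    tree = _yule_rooted(n_leaves, rng, mean_branch_length, prefix)
    tree.deroot()
    return tree


def _yule_rooted(n_leaves: int, rng: np.random.Generator,
                 mean_branch_length: float, prefix: str) -> dendropy.Tree:
    labels = [f"{prefix}{i + 1:02d}" for i in range(n_leaves)]
    ns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.is_rooted = True
    root = tree.seed_node
    leaves = []
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        leaves.append(child)
    while len(leaves) < n_leaves:
        idx = int(rng.integers(len(leaves)))
        node = leaves.pop(idx)
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            leaves.append(child)
    # deterministic label order: left-to-right leaf order
    ordered = [n for n in tree.leaf_node_iter()]
    for label, node in zip(labels, ordered):
        node.taxon = ns.get_taxon(label)
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node:
            edge.length = float(rng.exponential(mean_branch_length))
    return tree


def evolve_family(tree: dendropy.Tree, length: int, rate: float, seed
                  ) -> tuple[dict[str, str], str]:
    """Evolve one protein family along a tree.

    The ancestral sequence is uniform over the 20 residues; along each
    branch a Poisson(rate * branch_length * length) number of
    substitution events hits uniformly chosen sites, each replacing the
    residue with one of the 19 others.  No indels are introduced.
    Returns (leaf label -> sequence, ancestral sequence).
    """
    if length < 50:
        raise ValueError("length must be >= 50")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    root_seq = rng.integers(0, N_AA, size=length).astype(np.uint8)
    seqs: dict[str, str] = {}

    def descend(node, seq: np.ndarray) -> None:
        for child in node.child_nodes():
            bl = child.edge.length or 0.0
            child_seq = seq.copy()
            n_sub = int(rng.poisson(rate * bl * length))
            for _ in range(n_sub):
                pos = int(rng.integers(length))
                old = child_seq[pos]
                new = int(rng.integers(N_AA - 1))
                child_seq[pos] = new if new < old else new + 1
            if child.is_leaf():
                seqs[child.taxon.label] = _decode(child_seq)
            else:
                descend(child, child_seq)

    descend(tree.seed_node, root_seq)
    return seqs, _decode(root_seq)


def _decode(codes: np.ndarray) -> str:
    return "".join(ALPHABET[c] for c in codes)


def plant_csi(family_sequences: dict[str, str], root_seq: str,
              tree: dendropy.Tree, clade_leaves: set[str], event_type: str,
              size: int, position: int, seed, clade_name: str = "ingroup",
              family_id: str = "?", lock_flanks: bool = True
              ) -> tuple[dict[str, str], CsiEvent]:
    """Plant one clade-specific indel into an evolved family.

    ``position`` is a 1-based offset in ancestral coordinates: an
    insertion adds a fixed random segment *after* that position in every
    clade leaf (identical across carriers); a deletion removes residues
    ``position .. position+size-1`` from every clade leaf.  Unless
    ``lock_flanks`` is false, the 20 residues on each side of the edit
    point revert to the ancestral residues in *all* leaves so the flanks
    are conserved by construction.
    """
    if size < 1:
        raise ValueError("indel size must be >= 1")
    length = len(root_seq)
    if event_type not in ("insertion", "deletion"):
        raise ValueError(f"unknown event type {event_type!r}")
    if event_type == "deletion" and position + size - 1 > length:
        raise ValueError("deletion extends past the sequence end")
    lo_flank = range(max(0, position - _FLANK_LOCK), position)
    if event_type == "insertion":
        hi_flank = range(position, min(length, position + _FLANK_LOCK))
    else:
        hi_flank = range(position + size - 1,
                         min(length, position + size - 1 + _FLANK_LOCK))
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    segment = _decode(rng.integers(0, N_AA, size=size).astype(np.uint8))
    missing = clade_leaves - set(family_sequences)
    if missing:
        raise ValueError(f"clade leaves absent from family: {sorted(missing)}")
    out: dict[str, str] = {}
    for leaf, seq in family_sequences.items():
        if lock_flanks:
            chars = list(seq)
            for c in lo_flank:
                chars[c] = root_seq[c]
            for c in hi_flank:
                chars[c] = root_seq[c]
            seq = "".join(chars)
        if leaf in clade_leaves:
            if event_type == "insertion":
                seq = seq[:position] + segment + seq[position:]
            else:
                seq = seq[:position - 1] + seq[position - 1 + size:]
        out[leaf] = seq
    event = CsiEvent(family_id=family_id, clade=clade_name,
                     event_type=event_type, size=size, position=position,
                     leaves=tuple(sorted(clade_leaves)))
    return out, event


def true_family_alignment(sequences: dict[str, str], event: CsiEvent | None,
                          seq_ids: dict[str, str] | None = None) -> Msa:
    """The by-construction alignment of a simulated family (gaps exactly
    at the planted indel)."""
    records = []
    for leaf in sorted(sequences):
        seq = sequences[leaf]
        if event is not None:
            carrier = leaf in event.leaves
            if event.event_type == "insertion" and not carrier:
                seq = seq[:event.position] + "-" * event.size + seq[event.position:]
            elif event.event_type == "deletion" and carrier:
                seq = seq[:event.position - 1] + "-" * event.size + \
                    seq[event.position - 1:]
        rec_id = (seq_ids or {}).get(leaf, leaf)
        records.append(SequenceRecord(rec_id, leaf, seq))
    return Msa(records)


def _assert_detectable(sequences: dict[str, str], event: CsiEvent,
                       groups: GroupAssignment) -> None:
    """Planted events must be recoverable at default scan parameters."""
    msa = true_family_alignment(sequences, event)
    cands = find_csi_candidates(msa, groups, CsiParams())
    for c in cands:
        width = c.alignment_interval[1] - c.alignment_interval[0] + 1
        if width == event.size and c.size_range == (event.size, event.size):
            return
    raise AssertionError(
        f"planted {event.event_type} of size {event.size} in "
        f"{event.family_id} is not detectable at default parameters")


def generate_dataset(config: SimConfig
                     ) -> tuple[ProteomeSet, GroupAssignment, SimManifest]:
    """Full synthetic study: tree, families, planted events, noise.

    Deterministic given ``config.seed``; every planted CSI is asserted
    detectable at default scan parameters unless ``hard_mode`` is set.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    in_tree = _yule_rooted(config.n_ingroup, rng, config.branch_length_mean,
                           "IN")
    out_tree = _yule_rooted(config.n_outgroup, rng, config.branch_length_mean,
                            "OUT")
    labels = [f"IN{i + 1:02d}" for i in range(config.n_ingroup)] + \
             [f"OUT{i + 1:02d}" for i in range(config.n_outgroup)]
    ns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.is_rooted = True
    for sub in (in_tree, out_tree):
        node = sub.seed_node
        tree.seed_node.add_child(node)
        node.edge.length = config.stem_length
    tree.migrate_taxon_namespace(ns)
    ingroup = {f"IN{i + 1:02d}" for i in range(config.n_ingroup)}
    outgroup = {f"OUT{i + 1:02d}" for i in range(config.n_outgroup)}
    groups = GroupAssignment(
        groups={"ingroup": set(ingroup), "outgroup": set(outgroup)},
        focal_group="ingroup")

    sizes = config.resolved_csi_sizes()
    patchy = set(range(config.n_csi,
                       min(config.n_csi + config.n_patchy_families,
                           config.n_families)))
    genomes: dict[str, list[SequenceRecord]] = {g: [] for g in labels}
    manifest = SimManifest(
        true_tree=tree.as_string(schema="newick").strip(), families={})
    for fi in range(config.n_families):
        family_id = f"SIM{fi + 1:04d}"
        seqs, root_seq = evolve_family(tree, config.family_length,
                                       config.substitution_rate, rng)
        event = None
        if fi < config.n_csi:
            size = sizes[fi]
            event_type = "insertion" if fi % 2 == 0 else "deletion"
            lo = _FLANK_LOCK + 10
            hi = config.family_length - _FLANK_LOCK - 10 - size
            position = int(rng.integers(lo, hi + 1))
            seqs, event = plant_csi(
                seqs, root_seq, tree, ingroup, event_type, size, position,
                rng, clade_name="ingroup", family_id=family_id,
                lock_flanks=not config.hard_mode)
            if not config.hard_mode:
                _assert_detectable(seqs, event, groups)
            manifest.csi_events.append(event)
        present = set(seqs)
        if fi in patchy:
            k = max(1, int(0.3 * len(labels)))
            drop = rng.choice(sorted(present), size=k, replace=False)
            present -= set(drop)
        fam_members: dict[str, str] = {}
        for leaf in sorted(present):
            seq_id = f"{leaf}_{family_id}"
            genomes[leaf].append(SequenceRecord(seq_id, leaf, seqs[leaf]))
            fam_members[leaf] = seq_id
        manifest.families[family_id] = fam_members
    # clade-restricted genes: evolved on the ingroup subtree only
    for ci in range(config.n_csp):
        gene_id = f"CSP{ci + 1:03d}"
        seqs, _ = evolve_family(in_tree, config.csp_length,
                                config.substitution_rate, rng)
        members = []
        for leaf in sorted(seqs):
            seq_id = f"{leaf}_{gene_id}"
            genomes[leaf].append(SequenceRecord(seq_id, leaf, seqs[leaf]))
            members.append(seq_id)
        manifest.csp_events.append(CspEvent(
            gene_id=gene_id, clade="ingroup", member_ids=tuple(members)))
    # unrelated noise proteins
    lo, hi = config.noise_length_range
    for leaf in labels:
        for ni in range(config.n_noise_proteins):
            nid = f"{leaf}_NOISE{ni + 1:02d}"
            length = int(rng.integers(lo, hi + 1))
            seq = _decode(rng.integers(0, N_AA, size=length).astype(np.uint8))
            genomes[leaf].append(SequenceRecord(nid, leaf, seq))
            manifest.noise_ids.append(nid)
    return ProteomeSet(genomes), groups, manifest
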