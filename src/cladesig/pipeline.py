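"""End-to-end pipeline orchestration, configuration and report assembly.

Chains cluster -> align -> trim -> concatenate -> tree -> CSI scan ->
CSP scan over a proteome set and a group assignment, writing
tab-separated reports plus a run log into a run directory.  All stage
parameters live in one :class:`PipelineConfig`, loadable from an INI
file (``key = value`` under section headers); unknown keys are
rejected.  Reruns with the same config, inputs and seed produce
byte-identical reports.
"""

from __future__ import annotations

import configparser
import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .core_families import (cluster_proteomes, family_table_rows,
                            select_core_families)
from .csi_detect import CsiCandidate, CsiParams, find_csi_candidates, map_region
from .csp_detect import CspCall, call_csps, csp_report_rows, mini_search
from .msa_pipeline import TrimParams, align_family, concatenate, trim_blocks
from .sequence_io import (GroupAssignment, ProteomeSet, write_fasta,
                          write_hit_table, write_newick)
from .synthetic_data import SimConfig
from .tree_builder import bootstrap_support, distance_matrix, midpoint_root, \
    neighbor_joining

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class ClusterConfig:
    id_threshold: float = 0.50
    cov_threshold: float = 0.50
    presence_threshold: float = 0.80

    def validate(self) -> None:
        for name in ("id_threshold", "cov_threshold", "presence_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")


@dataclass
class CspConfig:
    evalue_threshold: float = 1e-5
    max_exceptions: int = 0
    score_threshold: float = 60.0
    query_genome: str = ""   # default: first focal genome alphabetically

    def validate(self) -> None:
        if self.evalue_threshold <= 0:
            raise ValueError("evalue_threshold must be > 0")
        if self.max_exceptions < 0:
            raise ValueError("max_exceptions must be >= 0")


@dataclass
class TreeConfig:
    model: str = "poisson"
    bootstrap_replicates: int = 0

    def validate(self) -> None:
        if self.model not in ("p", "poisson"):
            raise ValueError(f"unknown distance model {self.model!r}")
        if self.bootstrap_replicates < 0:
            raise ValueError("bootstrap_replicates must be >= 0")


@dataclass
class PipelineConfig:
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    trim: TrimParams = field(default_factory=TrimParams)
    csi: CsiParams = field(default_factory=CsiParams)
    csp: CspConfig = field(default_factory=CspConfig)
    tree: TreeConfig = field(default_factory=TreeConfig)
    sim: SimConfig = field(default_factory=SimConfig)
    seed: int = 0
    output_dir: str = "run"

    def validate(self) -> None:
        self.cluster.validate()
        self.csp.validate()
        self.tree.validate()
        if not 0 < self.trim.conserved_min_fraction < 1:
            raise ValueError("trim.conserved_min_fraction must be in (0, 1)")
        if not 0 <= self.trim.max_gap_fraction <= 1:
            raise ValueError("trim.max_gap_fraction must be in [0, 1]")
        # CsiParams and SimConfig validate themselves on construction/use


_SECTIONS = {
    "clustering": ("cluster", ClusterConfig),
    "trim": ("trim", TrimParams),
    "csi": ("csi", CsiParams),
    "csp": ("csp", CspConfig),
    "tree": ("tree", TreeConfig),
    "sim": ("sim", SimConfig),
}


def load_config(path: str | Path) -> PipelineConfig:
    """Parse an INI-style config; unknown sections or keys are errors."""
    parser = configparser.ConfigParser()
    with open(path) as fh:
        parser.read_file(fh)
    config = PipelineConfig()
    for section in parser.sections():
        if section == "run":
            for key, value in parser.items("run"):
                if key == "seed":
                    config.seed = int(value)
                elif key == "output_dir":
                    config.output_dir = value
                else:
                    raise ValueError(f"unknown key {key!r} in section [run]")
            continue
        if section not in _SECTIONS:
            raise ValueError(f"unknown config section [{section}]")
        attr, cls = _SECTIONS[section]
        fields = {f.name: f for f in dataclasses.fields(cls)}
        updates = {}
        for key, value in parser.items(section):
            if key not in fields:
                raise ValueError(f"unknown key {key!r} in section [{section}]")
            ftype = fields[key].type
            if key == "csi_sizes":
                updates[key] = [int(x) for x in
                                value.replace(",", " ").split()]
            elif key == "noise_length_range":
                lo, hi = (int(x) for x in value.replace(",", " ").split())
                updates[key] = (lo, hi)
            elif ftype in ("int", int):
                updates[key] = int(value)
            elif ftype in ("float", float):
                updates[key] = float(value)
            elif ftype in ("bool", bool):
                updates[key] = value.lower() in ("1", "true", "yes")
            else:
                updates[key] = value
        setattr(config, attr,
                dataclasses.replace(getattr(config, attr), **updates))
    config.validate()
    return config


# ---------------------------------------------------------------------------

def _write_tsv(path: Path, header: list[str], rows: list[tuple]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def render_table_report(candidates: list[CsiCandidate],
                        csps: list[CspCall],
                        lengths: dict[str, int] | None = None
                        ) -> tuple[str, str]:
    """Publication-style tab-separated tables for CSIs and CSPs."""
    csi_lines = ["\t".join(["family_id", "reference_id", "indel_size",
                            "indel_region", "specificity",
                            "ingroup_violators", "outgroup_violators"])]
    for c in candidates:
        region = f"{c.region[0]}–{c.region[1]}" if c.region else ""
        csi_lines.append("\t".join([
            c.family_id or "?", c.reference_id or "", c.size_label, region,
            "focal group", ";".join(c.ingroup_violators),
            ";".join(c.outgroup_violators)]))
    csp_lines = ["\t".join(["query_id", "length", "function",
                            "specificity"])]
    for row in csp_report_rows(csps, lengths):
        csp_lines.append("\t".join(row))
    return "\n".join(csi_lines) + "\n", "\n".join(csp_lines) + "\n"


def run_pipeline(config: PipelineConfig, proteomes: ProteomeSet,
                 groups: GroupAssignment) -> Path:
    """Execute the full discovery chain and write all reports.

    Returns the run directory containing: families.tsv,
    supermatrix.fasta, partitions.tsv, tree.nwk, csi_candidates.tsv,
    csp_report.tsv, csp_hits.tsv and run.log.
    """
    config.validate()
    proteomes.require_pipeline_ready()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [
        f"cladesig {__version__}",
        f"seed {config.seed}",
        f"genomes {proteomes.n_genomes}",
        f"params cluster={config.cluster} trim={config.trim} "
        f"csi={config.csi} csp={config.csp} tree={config.tree}",
    ]

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(name, str(exc)) from exc

    # 1. clustering
    families = stage("cluster", cluster_proteomes, proteomes,
                     config.cluster.id_threshold, config.cluster.cov_threshold)
    core = stage("cluster", select_core_families, families,
                 config.cluster.presence_threshold)
    logger.info("clustering: %d families, %d core", len(families), len(core))
    log_lines.append(f"families {len(families)} core {len(core)}")
    _write_tsv(out / "families.tsv",
               ["family_id", "seed_id", "genome", "member_id", "identity",
                "coverage"], family_table_rows(core))

    # 2-3. align and trim each core family
    msas = []
    trimmed = []
    for fam in core:
        msa = stage("align", align_family, fam)
        msas.append(msa)
        trimmed.append(stage("trim", trim_blocks, msa, config.trim))
    total_trimmed = sum(t.length for t in trimmed)
    logger.info("alignment: %d families, %d trimmed columns",
                len(msas), total_trimmed)
    log_lines.append(f"trimmed_columns {total_trimmed}")

    # 4. supermatrix + tree
    genome_list = sorted(proteomes.genomes)
    supermatrix = stage("concat", concatenate, trimmed, genome_list)
    write_fasta(supermatrix.records, out / "supermatrix.fasta")
    _write_tsv(out / "partitions.tsv", ["family_id", "start", "end"],
               supermatrix.partitions)
    log_lines.append(f"supermatrix_columns {supermatrix.length}")
    if config.tree.bootstrap_replicates > 0:
        tree = stage("tree", bootstrap_support, supermatrix,
                     config.tree.bootstrap_replicates, config.seed,
                     config.tree.model)
    else:
        tree = stage("tree", neighbor_joining,
                     stage("tree", distance_matrix, supermatrix,
                           config.tree.model))
    rooted = stage("tree", midpoint_root, tree)
    write_newick(rooted, out / "tree.nwk")

    # 5. CSI scan over the untrimmed family alignments
    candidates: list[CsiCandidate] = []
    skipped = 0
    for msa in msas:
        focal_in_msa = sorted(r.id for r in msa.records
                              if groups.membership(r.taxon) == "focal")
        try:
            found = find_csi_candidates(msa, groups, config.csi)
        except ValueError:
            skipped += 1
            continue
        for cand in found:
            if focal_in_msa:
                cand.reference_id = focal_in_msa[0]
                try:
                    cand.region = map_region(cand, msa, cand.reference_id,
                                             config.csi, groups)
                except ValueError:
                    pass
            candidates.append(cand)
    logger.info("csi-scan: %d candidates (%d families skipped)",
                len(candidates), skipped)
    log_lines.append(f"csi_candidates {len(candidates)} "
                     f"csi_skipped_families {skipped}")

    # 6. CSP scan
    query_genome = config.csp.query_genome or \
        next(g for g in genome_list if groups.membership(g) == "focal")
    if query_genome not in proteomes.genomes:
        raise PipelineError("csp-scan",
                            f"query genome {query_genome!r} not in proteomes")
    hits = stage("csp-scan", mini_search, proteomes.genomes[query_genome],
                 proteomes, config.csp.score_threshold)
    write_hit_table(hits, out / "csp_hits.tsv")
    calls = stage("csp-scan", call_csps, hits, groups,
                  config.csp.evalue_threshold, config.csp.max_exceptions)
    n_specific = sum(1 for c in calls if c.verdict == "specific")
    logger.info("csp-scan: %d queries, %d specific", len(calls), n_specific)
    log_lines.append(f"csp_queries {len(calls)} csp_specific {n_specific}")

    lengths = {r.id: len(r.residues)
               for r in proteomes.genomes[query_genome]}
    csi_table, csp_table = render_table_report(candidates, calls, lengths)
    (out / "csi_candidates.tsv").write_text(
        "# specificity relative to the supplied comparison universe\n"
        + csi_table)
    (out / "csp_report.tsv").write_text(
        "# specificity relative to the supplied comparison universe\n"
        + csp_table)
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out
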