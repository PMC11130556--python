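"""End-to-end orchestration of the barcode analysis stages.

``run_pipeline`` consumes an aligned FASTA plus a labels TSV and writes, in
order: the distance matrix CSV, per-species profiles (TSV + text report), the
threshold partition, the ranked-partition report, congruence comparisons
against the labels (and against any externally produced partitions), and the
diagnostic-indel report when a reference record is named.  A run log records
package version, configuration and seed.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .characterise import all_profiles, characterisation_report, write_profiles_tsv
from .delimit import (
    DEFAULT_THRESHOLD,
    compare_partition,
    ranked_partitions,
    ranked_partitions_report,
    read_partition_tsv,
    single_linkage_clusters,
    write_comparison_tsv,
    write_partition_tsv,
)
from .diagnose import (
    DEFAULT_EXPECTED_LENGTH,
    DEFAULT_EXPECTED_REGION,
    diagnose_genus,
    diagnostic_report,
)
from .distances import DistancePolicy, distance_matrix
from .seqio import read_alignment, write_distance_csv


class StageError(RuntimeError):
    """An identifiable pipeline stage failed."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    alignment: Path
    labels: Path | None = None
    external_partitions: list[Path] = field(default_factory=list)
    policy: DistancePolicy = DistancePolicy.STRICT
    majority: float = 0.5
    threshold: float = DEFAULT_THRESHOLD
    reference_id: str | None = None
    expected_length: int = DEFAULT_EXPECTED_LENGTH
    expected_region: tuple[int, int] = DEFAULT_EXPECTED_REGION
    outdir: Path = Path("barcodegap_out")
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie strictly between 0 and 1")


def parse_threshold(text: str) -> float:
    """Accept either a fraction ("0.03") or a percentage ("3%")."""
    text = text.strip()
    if text.endswith("%"):
        return float(text[:-1]) / 100.0
    return float(text)


def run_pipeline(cfg: RunConfig, log=sys.stderr) -> dict[str, Path]:
    """Run every stage, returning the artifact paths keyed by stage name."""
    cfg.validate()
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def stage(name: str, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - stage-named abort is the contract
            raise StageError(name, exc) from exc

    aln = stage("read_alignment", lambda: read_alignment(cfg.alignment, cfg.labels))
    labels = aln.labels

    m = stage("distances", lambda: distance_matrix(aln, cfg.policy))
    artifacts["distances"] = cfg.outdir / "distances.csv"
    stage("distances", lambda: write_distance_csv(m, artifacts["distances"]))

    profiles = stage(
        "characterise", lambda: all_profiles(aln, labels, cfg.policy, cfg.majority)
    )
    artifacts["profiles"] = cfg.outdir / "species_profiles.tsv"
    artifacts["report"] = cfg.outdir / "characterisation.txt"
    write_profiles_tsv(profiles, artifacts["profiles"])
    artifacts["report"].write_text(characterisation_report(profiles))

    part = stage("delimit", lambda: single_linkage_clusters(m, cfg.threshold))
    artifacts["partition"] = cfg.outdir / "partition.tsv"
    write_partition_tsv(part, artifacts["partition"])

    if len(aln) >= 3:
        ranked = stage("ranked_partitions", lambda: ranked_partitions(m))
        artifacts["ranked"] = cfg.outdir / "ranked_partitions.tsv"
        artifacts["ranked"].write_text(ranked_partitions_report(ranked))

    cmp_ref = stage("compare", lambda: compare_partition(part, labels))
    artifacts["comparison"] = cfg.outdir / "comparison_vs_labels.tsv"
    write_comparison_tsv(cmp_ref, artifacts["comparison"])
    for i, ext in enumerate(cfg.external_partitions, start=1):
        ext_part = stage("compare_external", lambda e=ext: read_partition_tsv(e))
        ext_cmp = stage("compare_external", lambda p=ext_part: compare_partition(p, labels))
        key = f"comparison_external_{i}"
        artifacts[key] = cfg.outdir / f"{key}.tsv"
        write_comparison_tsv(ext_cmp, artifacts[key])

    if cfg.reference_id is not None:
        verdict = stage(
            "diagnose",
            lambda: diagnose_genus(
                aln,
                cfg.reference_id,
                expected_length=cfg.expected_length,
                expected_region=cfg.expected_region,
            ),
        )
        artifacts["diagnostic"] = cfg.outdir / "diagnostic.txt"
        artifacts["diagnostic"].write_text(diagnostic_report(verdict))

    artifacts["log"] = cfg.outdir / "run_log.txt"
    artifacts["log"].write_text(
        f"barcodegap {__version__}\n"
        f"alignment: {cfg.alignment}\nlabels: {cfg.labels}\n"
        f"policy: {cfg.policy.value}\nmajority: {cfg.majority}\n"
        f"threshold: {cfg.threshold}\nreference_id: {cfg.reference_id}\n"
        f"seed: {cfg.seed}\n"
    )
    print(f"wrote {len(artifacts)} artifacts to {cfg.outdir}", file=log)
    return artifacts
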