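"""End-to-end orchestration: config, staging, and comparison reports."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd
import yaml

from .enrichment import EnrichmentParams, enrichment_summary
from .landscape import HaplotypeLandscape, read_landscape, write_landscape
from .model import (
    InstabilityParams,
    relative_stabilities,
    stability_report,
    stability_variation,
)
from .regions import GenomicInterval
from .scanner import (
    QueryMotif,
    RevCompHit,
    ScanParams,
    scan_landscape,
    write_hits_bed,
    write_hits_tsv,
)
from .simulate import PhaseSpec, SyntheticLandscapeSpec, generate_haplotype_set

logger = logging.getLogger("invstab")


class StageError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Serialisable end-to-end run configuration; defaults are the study constants."""

    output_dir: str = "invstab_out"
    seed: int = 0
    landscapes: List[str] = field(default_factory=list)  # FASTA paths
    blocks: List[Optional[str]] = field(default_factory=list)  # BED paths (parallel)
    query_region: Optional[str] = None  # "chrom:start-end", 1-based inclusive
    simulate: bool = False
    sim_length: int = 1_000_001
    n_haplotypes: int = 5
    absence_count: int = 21
    scan: ScanParams = field(default_factory=ScanParams)
    model: InstabilityParams = field(default_factory=InstabilityParams)
    enrichment: EnrichmentParams = field(default_factory=EnrichmentParams)
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, typ in (("scan", ScanParams), ("model", InstabilityParams), ("enrichment", EnrichmentParams)):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @property
    def config_hash(self) -> str:
        """Hash of the scientific parameters (paths and logging excluded)."""
        d = self.to_dict()
        for key in ("output_dir", "log_level"):
            d.pop(key, None)
        payload = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def run_compare(
    per_haplotype: Dict[str, Sequence[RevCompHit]],
    model_params: InstabilityParams = InstabilityParams(),
) -> Dict[str, object]:
    """Comparison report across >= 2 haplotypes sharing one query.

    Returns the per-haplotype table (mismatch-class counts, raw stability,
    relative %, leave-top-hit-out columns) plus the two variation lines.
    """
    if len(per_haplotype) < 2:
        raise ValueError("need >= 2 haplotypes to compare")
    table = stability_report(per_haplotype, model_params)
    variation = stability_variation(list(table["relative_pct"]))
    variation_excl = stability_variation(list(table["relative_excl_pct"]))
    return {
        "table": table,
        "variation_pct": variation,
        "variation_excl_pct": variation_excl,
    }


def run_end_to_end(config: RunConfig) -> Dict[str, object]:
    """simulate/load -> scan -> score -> compare -> enrichment, writing all artifacts."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    fh = logging.FileHandler(out / "run.log")
    logger.addHandler(fh)
    try:
        config.to_yaml(out / "config_used.yaml")
        logger.info("config hash %s", config.config_hash)

        # stage: inputs
        landscapes: Dict[str, HaplotypeLandscape] = {}
        try:
            if config.simulate:
                spec = SyntheticLandscapeSpec(seed=config.seed, length=config.sim_length)
                sim, truth = generate_haplotype_set(
                    spec, config.n_haplotypes, config.absence_count
                )
                truth.to_csv(out / "truth.tsv", sep="\t", index=False)
                for name, land in sim.items():
                    write_landscape(land, out / f"{name}.fa", out / f"{name}.blocks.bed")
                landscapes = sim
                query_iv = spec.query_interval
                query_seq = spec.query
            else:
                if not config.landscapes or config.query_region is None:
                    raise ValueError("need landscape FASTAs and a query region")
                query_iv = GenomicInterval.parse(config.query_region)
                blocks = config.blocks or [None] * len(config.landscapes)
                for path, bed in zip(config.landscapes, blocks):
                    land = read_landscape(path, blocks_path=bed, name=Path(path).stem)
                    landscapes[land.name] = land
                first = next(iter(landscapes.values()))
                query_seq = first.subseq(query_iv)
        except (OSError, ValueError, KeyError) as exc:
            raise StageError("input", str(exc)) from exc

        # stage: scan
        hits_by_hap: Dict[str, List[RevCompHit]] = {}
        try:
            for name, land in landscapes.items():
                query = QueryMotif(query_seq, query_iv)
                hits = scan_landscape(land, query, config.scan)
                hits_by_hap[name] = hits
                write_hits_tsv(hits, out / f"hits_{name}.tsv")
                write_hits_bed(hits, out / f"hits_{name}.bed")
                logger.info("%s: %d hits", name, len(hits))
        except (ValueError, KeyError) as exc:
            raise StageError("scan", str(exc)) from exc

        # stage: score + compare
        try:
            report = run_compare(hits_by_hap, config.model)
            table: pd.DataFrame = report["table"]
            table.insert(0, "config_hash", config.config_hash)
            table.to_csv(out / "compare.tsv", sep="\t", index=False)
            stability = {
                "config_hash": config.config_hash,
                "raw_stability": dict(zip(table["haplotype"], table["raw_stability"])),
                "relative_pct": dict(zip(table["haplotype"], table["relative_pct"])),
                "variation_pct": report["variation_pct"],
                "variation_excl_pct": report["variation_excl_pct"],
            }
            (out / "stability.json").write_text(json.dumps(stability, indent=2))
        except (ValueError, KeyError) as exc:
            raise StageError("score", str(exc)) from exc

        # stage: enrichment
        summary = enrichment_summary(config.enrichment)
        summary["config_hash"] = config.config_hash
        (out / "enrichment.json").write_text(json.dumps(summary, indent=2))
        return {"landscapes": landscapes, "hits": hits_by_hap, "report": report}
    finally:
        logger.removeHandler(fh)
        fh.close()
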