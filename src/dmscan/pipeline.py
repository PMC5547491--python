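"""Configuration-driven orchestration of a full analysis.

An experiment is a tree: experiment -> conditions -> selections (replicate
libraries over timepoints).  Each selection names either a pre-tabulated
variant x timepoint count TSV or per-timepoint sequencing libraries (FASTQ,
single/paired/barcoded).  Running an experiment produces per-selection
score tables, combined random-effects scores per condition, and optional
condition comparisons, all persisted as TSV with a config echo and a
plain-text log so the analysis can be re-run identically.

Config schema (JSON)::

    {
      "name": "experiment",
      "normalization": "wild-type",          # or "library-size"
      "min_quality": 20,
      "wild_type": "_wt",
      "reference": {"sequence": "ACGT...", "is_coding": true},   # optional
      "conditions": [
        {"name": "drug",
         "selections": [
           {"name": "rep1",
            "counts": "rep1_counts.tsv",     # pre-tabulated mode
            "timepoints": [0, 1, 2, 3]},     # optional with sidecar
           {"name": "rep2",                  # FASTQ mode
            "libraries": [
              {"timepoint": 0, "fastq": "t0.fq.gz"},
              {"timepoint": 1, "fastq_fwd": "...", "fastq_rev": "..."},
              {"timepoint": 2, "fastq": "...", "barcode_map": "map.tsv"}
            ]}
         ]}
      ]
    }
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from . import counting, refseq, scoring, replicates
from .analysis import compare_conditions

logger = logging.getLogger("dmscan")


class ConfigError(ValueError):
    """Invalid experiment configuration; message names the offending path."""


@dataclass
class ExperimentConfig:
    raw: dict
    base_dir: Path

    @classmethod
    def load(cls, path: Union[str, Path]) -> "ExperimentConfig":
        path = Path(path)
        try:
            raw = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ConfigError(f"{path}: not valid JSON ({exc})") from exc
        cfg = cls(raw, path.parent)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        root = self.raw
        if not isinstance(root, dict):
            raise ConfigError("config root must be an object")
        conditions = root.get("conditions")
        if not isinstance(conditions, list) or not conditions:
            raise ConfigError("conditions: must be a non-empty list")
        norm = root.get("normalization", "wild-type")
        if norm not in {"wild-type", "library-size"}:
            raise ConfigError(f"normalization: unknown mode {norm!r}")
        for ci, cond in enumerate(conditions):
            where = f"conditions[{ci}]"
            if "name" not in cond:
                raise ConfigError(f"{where}.name: missing")
            sels = cond.get("selections")
            if not isinstance(sels, list) or not sels:
                raise ConfigError(f"{where}.selections: must be a non-empty list")
            for si, sel in enumerate(sels):
                swhere = f"{where}.selections[{si}]"
                if "name" not in sel:
                    raise ConfigError(f"{swhere}.name: missing")
                has_counts = "counts" in sel
                has_libs = "libraries" in sel
                if has_counts == has_libs:
                    raise ConfigError(
                        f"{swhere}: exactly one of 'counts' or 'libraries' required"
                    )
                if has_libs:
                    libs = sel["libraries"]
                    if not isinstance(libs, list) or len(libs) < 2:
                        raise ConfigError(
                            f"{swhere}.libraries: need >= 2 timepoint libraries"
                        )
                    for li, lib in enumerate(libs):
                        if "timepoint" not in lib:
                            raise ConfigError(
                                f"{swhere}.libraries[{li}].timepoint: missing"
                            )
                    if "reference" not in root and not all(
                        "barcode_map" in lib for lib in libs
                    ):
                        raise ConfigError(
                            f"{swhere}: direct sequencing libraries need a "
                            "top-level reference"
                        )

    @property
    def normalization(self) -> str:
        return self.raw.get("normalization", "wild-type")

    @property
    def min_quality(self) -> int:
        return int(self.raw.get("min_quality", 20))

    @property
    def wild_type(self) -> str:
        return self.raw.get("wild_type", refseq.WILD_TYPE_LABEL)

    def reference(self) -> Optional[refseq.ReferenceSequence]:
        ref = self.raw.get("reference")
        if ref is None:
            return None
        return refseq.ReferenceSequence(
            ref["sequence"].upper(),
            is_coding=ref.get("is_coding", False),
            frame_offset=ref.get("frame_offset", 0),
            position_offset=ref.get("position_offset", 0),
        )

    def resolve(self, relpath: str) -> Path:
        p = Path(relpath)
        return p if p.is_absolute() else self.base_dir / p


def load_selection_table(
    config: ExperimentConfig, selection: dict
) -> counting.VariantCountTable:
    """Materialize one selection's count table from counts TSV or FASTQ."""
    if "counts" in selection:
        return counting.VariantCountTable.from_tsv(
            config.resolve(selection["counts"]),
            times=selection.get("timepoints"),
            wild_type=config.wild_type,
        )
    libs = sorted(selection["libraries"], key=lambda lib: lib["timepoint"])
    times = [float(lib["timepoint"]) for lib in libs]
    ref = config.reference()
    columns = {}
    totals = []
    for lib in libs:
        if "barcode_map" in lib:
            bmap = refseq.BarcodeMap.from_tsv(config.resolve(lib["barcode_map"]))
            reads = refseq.read_fastq(config.resolve(lib["fastq"]))
            counts, stats = refseq.count_reads(
                reads, barcode_map=bmap, min_quality=config.min_quality
            )
        else:
            if "fastq_rev" in lib:
                reads = refseq.read_fastq_pairs(
                    config.resolve(lib["fastq_fwd"]), config.resolve(lib["fastq_rev"])
                )
            else:
                reads = refseq.read_fastq(config.resolve(lib["fastq"]))
            counts, stats = refseq.count_reads(
                reads, ref=ref, min_quality=config.min_quality
            )
        logger.info(
            "library t=%s: %d reads, %d counted, %d quality-rejected, "
            "%d length-rejected, %d unmapped",
            lib["timepoint"], stats.total, stats.counted,
            stats.rejected_quality, stats.rejected_length, stats.rejected_unmapped,
        )
        columns[lib["timepoint"]] = counts
        totals.append(float(stats.counted))
    frame = pd.DataFrame(columns).fillna(0).astype(int)
    frame = frame.sort_index()
    return counting.VariantCountTable(
        frame,
        counting.TimepointSchedule(tuple(times)),
        read_totals=totals,
        wild_type=config.wild_type,
    )


def run_experiment(
    config: Union[str, Path, ExperimentConfig],
    output_dir: Union[str, Path],
) -> dict[str, pd.DataFrame]:
    """Run counts -> scores -> combined scores for every condition.

    Writes, under ``output_dir``: per-selection score TSVs, per-condition
    combined TSVs, a config echo, and a log.  Returns the combined score
    frame per condition name.  Deterministic given the same inputs.
    """
    if not isinstance(config, ExperimentConfig):
        config = ExperimentConfig.load(config)
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(output_dir / "dmscan.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        (output_dir / "config.json").write_text(json.dumps(config.raw, indent=1) + "\n")
        results: dict[str, pd.DataFrame] = {}
        for cond in config.raw["conditions"]:
            cname = cond["name"]
            logger.info("condition %s: %d selections", cname, len(cond["selections"]))
            score_frames = []
            for sel in cond["selections"]:
                table = load_selection_table(config, sel)
                scores = scoring.score_selection(table, config.normalization)
                out = output_dir / f"{cname}_{sel['name']}_scores.tsv"
                scoring.write_scores(scores, out)
                logger.info(
                    "selection %s: %d variants, %d scored (%s)",
                    sel["name"], len(scores),
                    int(scores["score"].notna().sum()),
                    scores["method"].iloc[0],
                )
                score_frames.append(scores)
            if len(score_frames) >= 2:
                combined = replicates.combine_replicates(score_frames)
            else:
                combined = score_frames[0][["score", "SE", "p_raw"]].copy()
                combined["n_reps"] = 1
            combined.to_csv(
                output_dir / f"{cname}_combined.tsv", sep="\t", index_label="variant"
            )
            results[cname] = combined
        names = list(results)
        if len(names) == 2:
            comparison = compare_conditions(results[names[0]], results[names[1]])
            comparison.to_csv(
                output_dir / f"{names[0]}_vs_{names[1]}.tsv",
                sep="\t",
                index_label="variant",
            )
        return results
    finally:
        logger.removeHandler(handler)
        handler.close()
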