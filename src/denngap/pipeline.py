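"""Orchestration of the screen → triage → conservation → kinetics chain.

Each ``run_*`` function wires the stage modules together for a
directory of inputs, logs counts, and writes a CSV report.  Failures
in one input (e.g. a single bad trace) are logged and do not abort the
remaining work.
"""

from __future__ import annotations

import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import kinetics, screen, structure

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    scores_dir: Path | None = None
    models_dir: Path | None = None
    reference_structure: Path | None = None
    msa: Path | None = None
    trace_dir: Path | None = None
    image_dir: Path | None = None
    output_dir: Path = Path(".")
    iptm_threshold: float = 0.6
    finger_cutoff: float = 4.5
    interface_cutoff: float = 4.0
    gap_mask_limit: float = 0.5
    gef_detection_fold: float = 2.0
    replicates: int = 3
    seed: int = 0
    ratio_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.iptm_threshold <= 1.0:
            raise ValueError("iptm_threshold outside [0, 1]")
        if self.finger_cutoff <= 0 or self.interface_cutoff <= 0:
            raise ValueError("distance cutoffs must be positive")
        if not 0.0 <= self.gap_mask_limit <= 1.0:
            raise ValueError("gap_mask_limit outside [0, 1]")

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        raw = tomllib.loads(Path(path).read_text())
        raw = {
            k: (Path(v) if k.endswith(("_dir", "structure", "msa")) and v else v)
            for k, v in raw.items()
        }
        if "ratio_pairs" in raw:
            raw["ratio_pairs"] = [tuple(p) for p in raw["ratio_pairs"]]
        return cls(**raw)


def run_screen(config: PipelineConfig) -> pd.DataFrame:
    """Parse → summarize → rank_and_filter over a score directory."""
    if config.scores_dir is None:
        raise ValueError("config.scores_dir is not set")
    paths = sorted(Path(config.scores_dir).glob("*.json"))
    if not paths:
        logger.warning("score directory %s is empty", config.scores_dir)
        frame = screen.summaries_to_frame([])
    else:
        scores = screen.parse_score_files(paths)
        logger.info("parsed %d model scores", len(scores))
        summaries = screen.summarize_pairs(scores, config.replicates)
        logger.info("summarised %d pairs", len(summaries))
        ranked = screen.rank_and_filter(summaries, config.iptm_threshold)
        logger.info(
            "%d of %d pairs plausible at ipTM >= %.2f",
            sum(s.plausible for s in ranked), len(ranked), config.iptm_threshold,
        )
        frame = screen.summaries_to_frame(ranked)
    out = Path(config.output_dir) / "ranked_pairs.csv"
    out.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(out, index=False)
    return frame


def run_triage(
    config: PipelineConfig,
    pair_model_path: str | Path,
    gtpase_chain: str = "G",
    candidate_chain: str = "A",
) -> pd.DataFrame:
    """Superpose, transplant GTP, and call candidate arginine fingers."""
    if config.reference_structure is None:
        raise ValueError("config.reference_structure is not set")
    ref = structure.read_structure(Path(config.reference_structure).read_text())
    model = structure.read_structure(Path(pair_model_path).read_text())
    if gtpase_chain not in model.chains():
        raise structure.StructureError(
            f"model lacks GTPase chain {gtpase_chain!r} (has {model.chains()})"
        )
    sup = structure.superpose(ref, model, None, gtpase_chain, gtpase_chain)
    logger.info("superposed %d Cα pairs, rmsd %.3f Å", sup.n_pairs, sup.rmsd)
    ligand = structure.transplant_ligand(ref, sup)
    calls = structure.detect_arginine_finger(
        model, ligand, candidate_chain, cutoff=config.finger_cutoff
    )
    frame = pd.DataFrame(
        [
            {
                "chain": c.chain_id,
                "residue": c.res_number,
                "residue_name": c.res_name,
                "min_distance_A": round(c.min_distance, 4),
                "passes": c.passes,
            }
            for c in calls
        ]
    )
    out = Path(config.output_dir) / "finger_calls.csv"
    out.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(out, index=False)
    return frame


def run_kinetics(config: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit every trace in the trace directory; emit rates and fold ratios.

    Each ``*.csv`` trace file must have ``time_s,fluorescence`` columns
    and a metadata sidecar ``*.json`` with ``gap_conc_M`` and ``label``.
    Returns (per-condition rate table, ratio table for the configured
    condition pairs).  A failing trace is logged and skipped.
    """
    if config.trace_dir is None:
        raise ValueError("config.trace_dir is not set")
    rows = []
    for csv_path in sorted(Path(config.trace_dir).glob("*.csv")):
        sidecar = csv_path.with_suffix(".json")
        try:
            meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
            frame = pd.read_csv(csv_path)
            trace = kinetics.FluorescenceTrace(
                times=frame["time_s"].to_numpy(),
                values=frame["fluorescence"].to_numpy(),
                gap_conc=meta.get("gap_conc_M"),
                label=meta.get("label", csv_path.stem),
            )
            fit = kinetics.fit_single_exponential(trace)
            rate = kinetics.gap_rate(fit, trace.gap_conc, trace.label)
        except (kinetics.TraceError, ValueError, KeyError) as exc:
            logger.error("trace %s failed: %s", csv_path.name, exc)
            continue
        rows.append(
            {
                "condition": rate.condition_id,
                "k_obs_s": rate.k_obs,
                "gap_conc_M": rate.gap_conc,
                "rate_M_s": rate.rate,
                "rate_1e4": rate.rate_1e4,
                "rmse": fit.rmse,
                "converged": fit.converged,
            }
        )
    rates = pd.DataFrame(rows)
    ratio_rows = []
    if not rates.empty:
        by_id = rates.set_index("condition")["rate_M_s"]
        for num, den in config.ratio_pairs:
            if num in by_id.index and den in by_id.index:
                ratio = float(by_id[num] / by_id[den])
                ratio_rows.append(
                    {
                        "numerator": num,
                        "denominator": den,
                        "ratio": ratio,
                        "ratio_rounded": int(round(ratio)),
                    }
                )
            else:
                logger.warning("ratio pair (%s, %s) not fully fitted", num, den)
    ratios = pd.DataFrame(ratio_rows)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    rates.to_csv(outdir / "gap_rates.csv", index=False)
    ratios.to_csv(outdir / "rate_ratios.csv", index=False)
    return rates, ratios
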