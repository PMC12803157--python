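"""Ranking of predicted-complex screens by interface confidence.

A structure-prediction screen produces several model replicates per
bait–prey pair, each with an interface predicted TM-score (ipTM) in
[0, 1] and optionally a predicted aligned error (PAE) matrix.  This
module parses the per-model score files, averages ipTM over replicates,
ranks the pairs, applies a plausibility threshold (inclusive, default
0.6), and summarises inter-chain PAE as a quantitative stand-in for
visual PAE-plot inspection.
"""

from __future__ import annotations

import json
import logging
import re
import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PAE_MAX = 31.75  # ceiling of the common emitter dialect

_NAME_RE = re.compile(r"^(?P<bait>.+?)__(?P<prey>.+?)__model(?P<idx>\d+)$")


class ScoreFileError(ValueError):
    """Raised for malformed or invalid score files."""


@dataclass(frozen=True)
class ModelScore:
    """Confidence scores for one predicted model of a bait–prey pair."""

    bait_id: str
    prey_id: str
    model_index: int
    iptm: float
    ptm: float | None = None
    pae: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.iptm <= 1.0:
            raise ScoreFileError(
                f"iptm {self.iptm} outside [0, 1] for "
                f"{self.bait_id}/{self.prey_id} model {self.model_index}"
            )
        if self.pae is not None:
            p = np.asarray(self.pae, dtype=float)
            if p.ndim != 2 or p.shape[0] != p.shape[1]:
                raise ScoreFileError("pae matrix must be square")


@dataclass(frozen=True)
class PairSummary:
    """One bait–prey pair's replicate-averaged screen result."""

    bait_id: str
    prey_id: str
    mean_iptm: float
    n_models: int
    plausible: bool = False
    rank: int | None = None
    interchain_pae_mean: float | None = None


def _pair_from_filename(path: Path) -> tuple[str, str, int]:
    m = _NAME_RE.match(path.stem)
    if m is None:
        raise ScoreFileError(
            f"cannot recover bait/prey ids from file name {path.name!r}; "
            "expected <bait>__<prey>__model<k>.json or a manifest"
        )
    return m.group("bait"), m.group("prey"), int(m.group("idx"))


def parse_score_files(
    paths: Iterable[str | Path],
    manifest: pd.DataFrame | None = None,
) -> list[ModelScore]:
    """Parse per-model JSON score files into :class:`ModelScore` records.

    Bait/prey identities come from a ``<bait>__<prey>__model<k>.json``
    file name, or from a *manifest* frame with columns
    ``path, bait_id, prey_id, model_index``.  Missing ``ptm``/``pae``
    keys are tolerated and recorded as absent.  PAE entries are clipped
    to [0, 31.75] Å with a warning.
    """
    lookup = None
    if manifest is not None:
        lookup = {
            str(Path(r.path).name): (str(r.bait_id), str(r.prey_id), int(r.model_index))
            for r in manifest.itertuples()
        }
    scores: list[ModelScore] = []
    for p in map(Path, paths):
        try:
            payload = json.loads(p.read_text())
        except json.JSONDecodeError as exc:
            raise ScoreFileError(f"malformed JSON in {p}: {exc}") from exc
        if lookup is not None and p.name in lookup:
            bait, prey, idx = lookup[p.name]
        else:
            bait, prey, idx = _pair_from_filename(p)
        if "iptm" not in payload:
            raise ScoreFileError(f"{p} lacks required 'iptm' key")
        pae = None
        if payload.get("pae") is not None:
            pae = np.asarray(payload["pae"], dtype=float)
            if pae.size and (pae.min() < 0.0 or pae.max() > PAE_MAX):
                logger.warning("PAE values in %s outside [0, %.2f]; clipping", p, PAE_MAX)
                pae = np.clip(pae, 0.0, PAE_MAX)
        scores.append(
            ModelScore(
                bait_id=bait,
                prey_id=prey,
                model_index=idx,
                iptm=float(payload["iptm"]),
                ptm=None if payload.get("ptm") is None else float(payload["ptm"]),
                pae=pae,
            )
        )
    return scores


def summarize_pairs(
    scores: Sequence[ModelScore],
    expected_replicates: int = 3,
    chain_lengths: dict[tuple[str, str], tuple[int, int]] | None = None,
) -> list[PairSummary]:
    """Average ipTM over the model replicates of each bait–prey pair.

    The mean is computed with exact rational arithmetic
    (:func:`statistics.mean`) so that a pair whose replicates all equal
    the plausibility threshold compares equal to it downstream.  Pairs
    with a replicate count different from *expected_replicates* are kept
    and logged.  When *chain_lengths* gives a ``(bait, prey)`` pair's
    per-chain residue counts, inter-chain PAE is averaged over the
    models that carry a PAE matrix.
    """
    by_pair: dict[tuple[str, str], list[ModelScore]] = {}
    for s in scores:
        by_pair.setdefault((s.bait_id, s.prey_id), []).append(s)
    out = []
    for (bait, prey), group in by_pair.items():
        if len(group) != expected_replicates:
            logger.warning(
                "pair %s/%s has %d models (expected %d)",
                bait, prey, len(group), expected_replicates,
            )
        pae_means: list[float] = []
        if chain_lengths is not None and (bait, prey) in chain_lengths:
            lengths = chain_lengths[(bait, prey)]
            pae_means = [
                interchain_pae(s.pae, lengths) for s in group if s.pae is not None
            ]
        out.append(
            PairSummary(
                bait_id=bait,
                prey_id=prey,
                mean_iptm=statistics.mean(s.iptm for s in group),
                n_models=len(group),
                interchain_pae_mean=(
                    statistics.mean(pae_means) if pae_means else None
                ),
            )
        )
    return out


def rank_and_filter(
    summaries: Sequence[PairSummary], iptm_threshold: float = 0.6
) -> list[PairSummary]:
    """Sort pairs by mean ipTM (descending) and flag plausible ones.

    The plausibility boundary is inclusive: ``mean_iptm >= threshold``.
    Ties are broken lexicographically by ``(bait_id, prey_id)`` so that
    ranking is deterministic.  Ranks are contiguous from 1.
    """
    if not 0.0 <= iptm_threshold <= 1.0:
        raise ValueError(f"iptm_threshold {iptm_threshold} outside [0, 1]")
    ordered = sorted(
        summaries, key=lambda s: (-s.mean_iptm, s.bait_id, s.prey_id)
    )
    return [
        PairSummary(
            bait_id=s.bait_id,
            prey_id=s.prey_id,
            mean_iptm=s.mean_iptm,
            n_models=s.n_models,
            plausible=s.mean_iptm >= iptm_threshold,
            rank=i + 1,
            interchain_pae_mean=s.interchain_pae_mean,
        )
        for i, s in enumerate(ordered)
    ]


def interchain_pae(
    pae: np.ndarray, chain_lengths: tuple[int, int]
) -> float:
    """Mean PAE over the two inter-chain blocks of a pair's PAE matrix.

    The mean covers both off-diagonal blocks (A→B and B→A) so the
    result is invariant to chain order.
    """
    pae = np.asarray(pae, dtype=float)
    la, lb = chain_lengths
    if pae.ndim != 2 or pae.shape[0] != pae.shape[1]:
        raise ValueError("pae must be a square matrix")
    if la + lb != pae.shape[0]:
        raise ValueError(
            f"chain lengths {la}+{lb} do not match matrix dimension {pae.shape[0]}"
        )
    top = pae[:la, la:]
    bottom = pae[la:, :la]
    return float(np.concatenate([top.ravel(), bottom.ravel()]).mean())


def summaries_to_frame(summaries: Sequence[PairSummary]) -> pd.DataFrame:
    """Ranked summaries as a DataFrame in the output CSV column order."""
    return pd.DataFrame(
        [
            {
                "bait_id": s.bait_id,
                "prey_id": s.prey_id,
                "mean_iptm": s.mean_iptm,
                "n_models": s.n_models,
                "plausible": s.plausible,
                "rank": s.rank,
                "interchain_pae_mean": s.interchain_pae_mean,
            }
            for s in summaries
        ]
    )
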