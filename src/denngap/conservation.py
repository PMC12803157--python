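"""Per-residue conservation from an MSA and surface-patch enrichment.

Conservation is scored per alignment column as one minus the
normalised Shannon entropy of the 20-state amino-acid frequency
vector (gaps excluded from the frequencies), so a fully conserved
column scores 1 and a uniformly variable one scores 0.  This is a
deliberate, transparent surrogate for phylogenetically weighted
scores such as Consurf's: what the downstream analysis needs is the
*relative* conservation of a candidate surface patch, which a
permutation test quantifies.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import AlignIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_LN20 = np.log(20.0)


class AlignmentError(ValueError):
    """Raised for unusable alignments or score lookups."""


@dataclass(frozen=True)
class ConservationTrack:
    """Conservation mapped to a reference sequence's residue numbers."""

    scores: Mapping[int, float]       # residue number -> score in [0, 1]
    masked: frozenset[int]            # residues whose column exceeded the gap limit
    reference_id: str

    def score(self, residue_number: int) -> float:
        if residue_number in self.masked:
            raise AlignmentError(f"residue {residue_number} is gap-masked")
        try:
            return self.scores[residue_number]
        except KeyError:
            raise AlignmentError(f"residue {residue_number} not in track") from None


@dataclass(frozen=True)
class PatchTest:
    patch: frozenset[int]
    background: frozenset[int]
    observed_mean: float
    p_value: float
    n_permutations: int
    seed: int


def read_msa(fasta_text: str):
    """Read an aligned FASTA into a Bio.Align MultipleSeqAlignment.

    Sequences are upper-cased and '.' gaps normalised to '-'; ragged
    record lengths raise :class:`AlignmentError`.
    """
    cleaned = []
    for line in fasta_text.splitlines():
        if line.startswith(">"):
            cleaned.append(line)
        else:
            cleaned.append(line.upper().replace(".", "-"))
    try:
        aln = AlignIO.read(io.StringIO("\n".join(cleaned)), "fasta")
    except ValueError as exc:
        raise AlignmentError(f"not a valid aligned FASTA: {exc}") from exc
    return aln


def _column_frequencies(column: str) -> tuple[np.ndarray, float]:
    counts = np.zeros(20)
    gaps = 0
    for ch in column:
        if ch == "-":
            gaps += 1
        elif ch in _AA_INDEX:
            counts[_AA_INDEX[ch]] += 1
        # ambiguous letters (X, B, Z, ...) are ignored like gaps but do
        # not count toward the gap fraction
    total = counts.sum()
    freqs = counts / total if total > 0 else counts
    return freqs, gaps / len(column)


def conservation_scores(
    alignment, reference_id: str, gap_mask_limit: float = 0.5
) -> ConservationTrack:
    """Per-reference-residue conservation scores in [0, 1].

    score = 1 − H/ln 20, H the Shannon entropy of the column's amino
    acid frequencies.  Columns with gap fraction above *gap_mask_limit*
    are masked; columns where the reference itself has a gap are
    dropped.  Residue numbering starts at 1 along the ungapped
    reference sequence.
    """
    ref = None
    for rec in alignment:
        if rec.id == reference_id:
            ref = str(rec.seq)
            break
    if ref is None:
        raise AlignmentError(f"reference {reference_id!r} not in alignment")
    scores: dict[int, float] = {}
    masked: set[int] = set()
    res_num = 0
    ncol = alignment.get_alignment_length()
    for col in range(ncol):
        if ref[col] == "-":
            continue
        res_num += 1
        column = alignment[:, col]
        freqs, gap_frac = _column_frequencies(column)
        if gap_frac > gap_mask_limit:
            masked.add(res_num)
            continue
        nz = freqs[freqs > 0]
        entropy = float(-(nz * np.log(nz)).sum()) if nz.size else _LN20
        scores[res_num] = max(0.0, 1.0 - entropy / _LN20)
    return ConservationTrack(
        scores=scores, masked=frozenset(masked), reference_id=reference_id
    )


def patch_conservation_test(
    track: ConservationTrack,
    patch_residues: Iterable[int],
    background_residues: Iterable[int],
    n_permutations: int = 10000,
    seed: int = 0,
) -> PatchTest:
    """Permutation test: is the patch more conserved than its surface?

    The observed statistic is the mean conservation over the patch; the
    null redraws patch-sized subsets (without replacement) from the
    pooled patch ∪ background scores.  The p-value carries the add-one
    correction ``(1 + #{null ≥ observed}) / (n + 1)`` and is therefore
    never zero.
    """
    patch = frozenset(patch_residues)
    background = frozenset(background_residues) - patch
    if not patch:
        raise AlignmentError("patch residue set is empty")
    if len(background) < len(patch):
        raise AlignmentError("background must be at least as large as the patch")
    patch_scores = np.array([track.score(r) for r in sorted(patch)])
    bg_scores = np.array([track.score(r) for r in sorted(background)])
    observed = float(patch_scores.mean())
    pooled = np.concatenate([patch_scores, bg_scores])
    rng = np.random.default_rng(seed)
    k = len(patch)
    # vectorised permutation: each row is one shuffled pool, statistic =
    # mean of its first k entries
    idx = np.argsort(
        rng.random((n_permutations, pooled.size)), axis=1
    )[:, :k]
    null = pooled[idx].mean(axis=1)
    p = float((1 + int((null >= observed).sum())) / (n_permutations + 1))
    return PatchTest(
        patch=patch,
        background=background,
        observed_mean=observed,
        p_value=p,
        n_permutations=n_permutations,
        seed=seed,
    )


def track_to_rows(track: ConservationTrack) -> list[dict]:
    """Rows (residue number, score, masked) for CSV output."""
    rows = [
        {"residue": r, "score": s, "masked": False}
        for r, s in sorted(track.scores.items())
    ]
    rows.extend(
        {"residue": r, "score": float("nan"), "masked": True}
        for r in sorted(track.masked)
    )
    rows.sort(key=lambda d: d["residue"])
    return rows
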