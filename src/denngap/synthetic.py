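"""Seed-deterministic generators for every input the pipeline consumes.

No structure-prediction output, crystal structure, alignment, kinetic
trace or micrograph is deposited with this package; each analysis
stage is instead exercised on synthetic inputs with planted ground
truth:

* score-file sets with controllable per-pair mean ipTM,
* a toy reference GTPase (with bound GTP) / predicted-complex pair in
  which a single catalytic arginine is planted at a chosen distance
  from the γ-phosphate,
* alignments with chosen conserved columns,
* single-exponential fluorescence traces parameterised by a packaged
  calibration table of published second-order GAP rates,
* two-channel punctate images with a chosen spot-overlap fraction.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .kinetics import FluorescenceTrace
from .structure import Atom, ComplexModel, write_structure


class ConstructionError(RuntimeError):
    """Raised when a generator cannot realise the requested geometry."""


# ------------------------------------------------------------ calibration

@dataclass(frozen=True)
class CalibrationCondition:
    """A published GAP-assay condition: second-order rate and [GAP]."""

    id: str
    rate: float        # M^-1 s^-1
    gap_conc: float    # M
    provenance: str    # "printed" or "derived"

    @property
    def k_obs(self) -> float:
        """Implied observed rate constant, s⁻¹ (rate × [GAP])."""
        return self.rate * self.gap_conc


#: Measured second-order GAP rates and the GAP concentrations used.
#: Rates for Avl9 on soluble ΔN-Arf1 (1 μM GAP), on membrane-bound
#: myristoylated Arf1 with and without prenylated Rab8 (1 nM GAP), and
#: DENND6A on ΔN-ARL8B (1 μM GAP) are published values; the Age2
#: benchmark is derived from the published statement that Avl9's rate
#: is tenfold higher than Age2's.
CALIBRATION_CONDITIONS: dict[str, CalibrationCondition] = {
    c.id: c
    for c in (
        CalibrationCondition("avl9_soluble_arf1", 1.5e4, 1e-6, "printed"),
        CalibrationCondition("avl9_myr_arf1", 69e4, 1e-9, "printed"),
        CalibrationCondition("avl9_myr_arf1_rab8", 480e4, 1e-9, "printed"),
        CalibrationCondition("dennd6a_arl8b", 0.18e4, 1e-6, "printed"),
        CalibrationCondition("age2_soluble_arf1", 0.15e4, 1e-6, "derived"),
    )
}


# ----------------------------------------------------------- trace maker

def make_trace(
    condition_or_k: CalibrationCondition | str | float,
    f0: float = 1.0,
    f_inf: float = 0.0,
    n_samples: int = 512,
    duration: float | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> FluorescenceTrace:
    """Single-exponential decay trace F(t) = f_inf + span·exp(−k t) + ε.

    *condition_or_k* may be a calibration condition (or its id), whose
    implied k_obs = rate × [GAP] is used and whose GAP concentration is
    copied into the trace metadata, or a bare k_obs in s⁻¹.  Sampling
    is uniform over [0, duration] (default duration 7/k_obs, about ten
    half-lives); ε is i.i.d. Normal(0, noise_sd).
    """
    gap_conc = None
    label = ""
    if isinstance(condition_or_k, str):
        try:
            condition_or_k = CALIBRATION_CONDITIONS[condition_or_k]
        except KeyError:
            raise KeyError(
                f"unknown calibration condition {condition_or_k!r}; "
                f"known: {sorted(CALIBRATION_CONDITIONS)}"
            ) from None
    if isinstance(condition_or_k, CalibrationCondition):
        k = condition_or_k.k_obs
        gap_conc = condition_or_k.gap_conc
        label = condition_or_k.id
    else:
        k = float(condition_or_k)
    if k <= 0:
        raise ValueError(f"k_obs must be positive, got {k}")
    if n_samples < 8:
        raise ValueError("need at least 8 samples")
    if duration is None:
        duration = 7.0 / k
    t = np.linspace(0.0, duration, n_samples)
    rng = np.random.default_rng(seed)
    values = f_inf + (f0 - f_inf) * np.exp(-k * t)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=n_samples)
    return FluorescenceTrace(times=t, values=values, gap_conc=gap_conc, label=label)


def write_trace(trace: FluorescenceTrace, csv_path: str | Path) -> Path:
    """Write a trace as time_s,fluorescence CSV with a metadata sidecar."""
    csv_path = Path(csv_path)
    lines = ["time_s,fluorescence"]
    lines += [f"{t:.10g},{v:.10g}" for t, v in zip(trace.times, trace.values)]
    csv_path.write_text("\n".join(lines) + "\n")
    sidecar = csv_path.with_suffix(".json")
    sidecar.write_text(
        json.dumps({"gap_conc_M": trace.gap_conc, "label": trace.label})
    )
    return csv_path


# ----------------------------------------------------------- score files

def make_score_records(
    specs: list[tuple[str, str, float]],
    out_dir: str | Path,
    jitter_sd: float = 0.01,
    replicates: int = 3,
    seed: int = 0,
) -> list[Path]:
    """Write per-model ipTM score files with exact per-pair means.

    For each ``(bait, prey, target_mean)`` spec, *replicates* ipTM
    values are drawn around the target and re-centred so their mean is
    the target; if re-centring would push a value outside [0, 1] the
    spread is shrunk until all values fit (a target of exactly 0 or 1
    therefore yields identical replicates).  Files follow the
    ``<bait>__<prey>__model<k>.json`` dialect.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    paths: list[Path] = []
    for bait, prey, target in specs:
        if not 0.0 <= target <= 1.0:
            raise ValueError(f"target mean ipTM {target} outside [0, 1]")
        deltas = rng.normal(0.0, jitter_sd, size=replicates) if jitter_sd > 0 else np.zeros(replicates)
        deltas -= deltas.mean()
        scale = 1.0
        for d in deltas:
            if d > 0 and target + d > 1.0:
                scale = min(scale, (1.0 - target) / d)
            elif d < 0 and target + d < 0.0:
                scale = min(scale, (0.0 - target) / d)
        values = target + scale * deltas
        for m, v in enumerate(values, start=1):
            p = out_dir / f"{bait}__{prey}__model{m}.json"
            p.write_text(json.dumps({"iptm": float(v), "ptm": float(v)}))
            paths.append(p)
    return paths


# ----------------------------------------------------------- toy complex

@dataclass(frozen=True)
class ToyComplexSpec:
    """Geometry of the planted arginine-finger fixture."""

    bait_residues: int = 150
    arginine_residue: int = 116
    nh1_pg_distance: float = 3.0   # Å
    seed: int = 7
    gtpase_chain: str = "G"
    bait_chain: str = "A"

    def __post_init__(self) -> None:
        if not 1 <= self.arginine_residue <= self.bait_residues:
            raise ConstructionError(
                f"planted residue {self.arginine_residue} outside "
                f"1..{self.bait_residues}"
            )
        if self.nh1_pg_distance <= 0:
            raise ConstructionError("planted distance must be positive")


_GTPASE_SEQ = "ACDEFGHIKLMNPQRSTVWY" * 2  # 40 residues, all 20 letters
_ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}

# GTP layout in the reference frame.  The arginine approaches along +x
# from the γ-phosphorus; γ-oxygens sit perpendicular to that axis and
# the β/α phosphorus atoms behind it, so the planted NH1–PG distance is
# the global guanidinium-to-γ-phosphate minimum by construction.
_GTP_ANCHOR = np.array([8.0, 0.0, 30.0])
_GTP_APPROACH = np.array([1.0, 0.0, 0.0])
_GTP_ATOMS = {
    "PG": np.zeros(3),
    "O1G": 1.5 * np.array([0.0, 1.0, 0.0]),
    "O2G": 1.5 * np.array([0.0, -0.5, np.sqrt(3) / 2]),
    "O3G": 1.5 * np.array([0.0, -0.5, -np.sqrt(3) / 2]),
    "PB": 1.6 * np.array([-1.0, 0.0, 0.0]),
    "PA": 3.2 * np.array([-1.0, 0.0, 0.0]),
}


def _helix_ca(n: int) -> np.ndarray:
    i = np.arange(n)
    theta = np.deg2rad(100.0) * i
    return np.column_stack(
        [2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i]
    )


def make_toy_complex(spec: ToyComplexSpec = ToyComplexSpec()) -> tuple[str, str]:
    """Build (reference PDB text, predicted-complex PDB text).

    The reference is a 40-residue Cα-only GTPase chain with a bound GTP
    (HETATM).  The predicted complex holds a rigidly transformed copy
    of that chain (transform drawn from the spec seed) plus a Cα-only
    bait chain in which only the planted residue is an arginine, its
    NH1 atom sitting exactly the requested distance from where the
    transplanted γ-phosphorus lands; every other bait residue is at
    least 10 Å from every GTP atom.
    """
    n_ref = len(_GTPASE_SEQ)
    ref_ca = _helix_ca(n_ref)
    ref_atoms = [
        Atom(spec.gtpase_chain, i + 1, _ONE_TO_THREE[_GTPASE_SEQ[i]], "CA", "C",
             tuple(np.round(ref_ca[i], 3)))
        for i in range(n_ref)
    ]
    for name, off in _GTP_ATOMS.items():
        ref_atoms.append(
            Atom(spec.gtpase_chain, 900, "GTP", name, name[0],
                 tuple(np.round(_GTP_ANCHOR + off, 3)))
        )
    reference = ComplexModel(atoms=ref_atoms)

    rng = np.random.default_rng(spec.seed)
    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.uniform(-20.0, 20.0, size=3)

    def move(x: np.ndarray) -> np.ndarray:
        return R @ x + t

    model_atoms = [
        Atom(spec.gtpase_chain, i + 1, _ONE_TO_THREE[_GTPASE_SEQ[i]], "CA", "C",
             tuple(np.round(move(ref_ca[i]), 3)))
        for i in range(n_ref)
    ]

    pg_t = move(_GTP_ANCHOR)  # where transplantation will put PG
    u = R @ _GTP_APPROACH
    w = R @ np.array([0.0, 1.0, 0.0])   # in-plane for the guanidinium
    w2 = R @ np.array([0.0, 0.0, 1.0])  # bait backbone direction
    d = spec.nh1_pg_distance
    cos50, sin50 = np.cos(np.deg2rad(50.0)), np.sin(np.deg2rad(50.0))
    arg_atoms = {
        "NH1": pg_t + d * u,
        "CZ": pg_t + (d + 1.33) * u,
        "NE": pg_t + (d + 1.33) * u + 1.33 * (cos50 * u + sin50 * w),
        "NH2": pg_t + (d + 1.33) * u + 1.33 * (cos50 * u - sin50 * w),
        "CA": pg_t + 14.0 * u,
    }
    # rounding to the 3-decimal PDB grid shifts each atom < 1e-3 Å; the
    # planted-distance contract (±0.01 Å) absorbs that
    for i in range(1, spec.bait_residues + 1):
        if i == spec.arginine_residue:
            for name in ("CA", "CZ", "NE", "NH1", "NH2"):
                el = "C" if name in ("CA", "CZ") else "N"
                model_atoms.append(
                    Atom(spec.bait_chain, i, "ARG", name, el,
                         tuple(np.round(arg_atoms[name], 3)))
                )
        else:
            ca = pg_t + 14.0 * u + (i - spec.arginine_residue) * 3.8 * w2
            model_atoms.append(
                Atom(spec.bait_chain, i, "ALA", "CA", "C",
                     tuple(np.round(ca, 3)))
            )
    model = ComplexModel(atoms=model_atoms)

    # verify the exclusion contract before emitting
    gtp_xyz = np.array([move(_GTP_ANCHOR + off) for off in _GTP_ATOMS.values()])
    for a in model.atoms:
        if a.chain_id == spec.bait_chain and a.res_number != spec.arginine_residue:
            dmin = np.linalg.norm(gtp_xyz - np.asarray(a.xyz), axis=1).min()
            if dmin < 10.0:
                raise ConstructionError(
                    f"bait residue {a.res_number} within 10 Å of GTP ({dmin:.2f})"
                )
    return write_structure(reference), write_structure(model)


# ------------------------------------------------------------------- MSA

def make_msa(
    reference_sequence: str,
    n_sequences: int = 50,
    conserved_positions: set[int] = frozenset(),
    substitution_rate: float = 0.3,
    seed: int = 0,
    reference_id: str = "REF",
) -> str:
    """Aligned FASTA: reference plus mutated homologs, no gaps.

    Positions are 1-based; positions in *conserved_positions* are never
    mutated, every other position mutates independently with the given
    per-site probability to a uniformly chosen different residue.
    """
    if not 0.0 <= substitution_rate <= 1.0:
        raise ValueError(f"substitution_rate {substitution_rate} outside [0, 1]")
    seq = reference_sequence.upper()
    bad = [p for p in conserved_positions if not 1 <= p <= len(seq)]
    if bad:
        raise ValueError(f"conserved positions outside sequence: {bad}")
    rng = np.random.default_rng(seed)
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    records = [(reference_id, seq)]
    for s in range(1, n_sequences):
        chars = list(seq)
        for pos in range(len(seq)):
            if (pos + 1) in conserved_positions:
                continue
            if rng.random() < substitution_rate:
                choices = alphabet.replace(chars[pos], "")
                chars[pos] = choices[rng.integers(len(choices))]
        records.append((f"seq{s}", "".join(chars)))
    return "\n".join(f">{rid}\n{rseq}" for rid, rseq in records) + "\n"


# ------------------------------------------------------------- two-channel

def make_two_channel(
    shape: tuple[int, int] = (256, 256),
    n_spots: int = 30,
    overlap_fraction: float = 0.5,
    spot_sigma: float = 2.0,
    noise_sd: float = 0.0,
    amplitude: float = 100.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Two punctate channels sharing a controlled fraction of spot centres.

    ``round(overlap_fraction × n_spots)`` Gaussian spots share centres
    across the channels; all remaining centres are kept at least
    6·sigma from every other centre, so non-shared spots contribute no
    cross-channel signal.  Returns (channel1, channel2, realised
    overlap fraction).
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_shared = int(round(overlap_fraction * n_spots))
    margin = 4.0 * spot_sigma
    min_sep = 6.0 * spot_sigma
    centers: list[np.ndarray] = []
    needed = n_shared + 2 * (n_spots - n_shared)
    for _ in range(needed):
        for _attempt in range(5000):
            c = rng.uniform([margin, margin],
                            [shape[0] - margin, shape[1] - margin])
            if all(np.linalg.norm(c - o) >= min_sep for o in centers):
                centers.append(c)
                break
        else:
            raise ConstructionError(
                f"could not pack {needed} spots at separation {min_sep:.1f} px "
                f"into {shape}"
            )
    shared = centers[:n_shared]
    only1 = centers[n_shared : n_spots]
    only2 = centers[n_spots : needed]

    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]

    def paint(spot_centers: list[np.ndarray]) -> np.ndarray:
        img = np.zeros(shape, dtype=float)
        for cy, cx in spot_centers:
            img += amplitude * np.exp(
                -((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * spot_sigma**2)
            )
        return img

    ch1 = paint(shared + only1)
    ch2 = paint(shared + only2)
    if noise_sd > 0:
        ch1 = np.clip(ch1 + rng.normal(0, noise_sd, shape), 0, None)
        ch2 = np.clip(ch2 + rng.normal(0, noise_sd, shape), 0, None)
    return ch1, ch2, n_shared / n_spots
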