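"""Synthetic trajectory generation with embedded ground truth.

Trajectories are generated *kinematically*: conformations are built from
scripted backbone/sidechain torsion schedules (no dynamics), then
zero-mean Gaussian coordinate jitter emulates thermal fluctuation.  Each
scenario follows a behavioural preset:

``stable``
    helical throughout; classifies as group A.
``partial_B``
    breaks two αHBs at a scripted time and stays partially unfolded;
    classifies as group B with no complete three-step verdict.
``refold_A``
    partially unfolds mid-run, then refolds well before the final 2 ns;
    group A.
``complete_C``
    the full three-step unfolding: sustained αHB loss at t₁, a nonpolar
    sidechain cluster producing the deepest E_np-np minimum at t₂, a
    polar-sidechain/salt-bridge E_p-p excursion at t₃, then an extended
    chain for the rest of the run; group C, verdict complete_three_step.

The conformational way-points (helical, open, partially unfolded,
clustered, polar-bridged, extended) are fixed torsion-space targets
constructed once for this generator; scenario scripts interpolate between
them on shortest angular paths with per-segment easing so the energy
extrema fall sharply at the scripted event times.

Ground truth (scripted event times and intended class) is returned with
every trajectory so detector and classifier accuracy can be scored
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._targets import TARGETS
from .builder import build_frames
from .topology import PeptideTopology, build_topology
from .trajectory import Trajectory

__all__ = [
    "SCENARIO_KINDS",
    "ScenarioScript",
    "GroundTruth",
    "make_scenario",
    "generate_trajectory",
    "ensemble_spec",
    "make_ensemble",
]

SCENARIO_KINDS = ("stable", "partial_B", "refold_A", "complete_C")

#: Default RMS Cartesian displacement per atom (Å) emulating thermal noise.
DEFAULT_JITTER = 0.25


@dataclass(frozen=True)
class ScenarioScript:
    """Recipe for one synthetic trajectory (times in ns)."""

    kind: str
    variant: str = "WT"
    protonation: str = "+"
    duration_ns: float = 20.0
    stride_ps: float = 10.0
    jitter: float = DEFAULT_JITTER
    seed: int = 0
    temperature_k: int = 360
    t1: float | None = None  # sustained αHB loss
    t2: float | None = None  # E_np-np minimum (hydrophobic cluster)
    t3: float | None = None  # E_p-p excursion (polar contacts)
    break_ns: float | None = None  # partial_B / refold_A unfolding time
    refold_ns: float | None = None  # refold_A recovery time

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.duration_ns <= 0 or self.stride_ps <= 0:
            raise ValueError("duration and stride must be positive")
        if self.kind == "complete_C":
            if not (self.t1 and self.t2 and self.t3):
                raise ValueError("complete_C script needs t1 < t2 < t3")
            if not self.t1 < self.t2 < self.t3:
                raise ValueError("event times must be ordered t1 < t2 < t3")
            if self.t2 - self.t1 > 0.5 + 1e-9:
                raise ValueError("step 2 must follow step 1 within 0.5 ns")
            if self.t3 - self.t2 > 1.5 + 1e-9:
                raise ValueError("step 3 must follow step 2 within 1.5 ns")

    @property
    def intended_group(self) -> str:
        return {"stable": "A", "refold_A": "A",
                "partial_B": "B", "complete_C": "C"}[self.kind]


@dataclass(frozen=True)
class GroundTruth:
    """Scripted truth carried alongside a generated trajectory."""

    kind: str
    variant: str
    protonation: str
    seed: int
    intended_group: str
    t1: float | None = None
    t2: float | None = None
    t3: float | None = None


def make_scenario(
    kind: str,
    variant: str = "WT",
    protonation: str = "+",
    seed: int = 0,
    **overrides,
) -> ScenarioScript:
    """Build a scenario script, sampling preset event times from ``seed``.

    ``complete_C`` samples t₁ ~ U(1, 16) ns, t₂ = t₁ + U(0.05, 0.5) and
    t₃ = t₂ + U(0.5, 1.5); ``partial_B``/``refold_A`` sample their
    unfolding (and refolding) times.  Keyword overrides replace any field
    of :class:`ScenarioScript`.  Deterministic in (kind, variant,
    protonation, seed, overrides).
    """
    if kind not in SCENARIO_KINDS:
        raise ValueError(f"unknown scenario kind {kind!r}")
    rng = np.random.default_rng([int(seed) % (2**31), SCENARIO_KINDS.index(kind)])
    fields: dict = {}
    if kind == "complete_C":
        t1 = rng.uniform(1.0, 16.0)
        t2 = t1 + rng.uniform(0.05, 0.5)
        t3 = t2 + rng.uniform(0.5, 1.5)
        fields.update(t1=round(t1, 3), t2=round(t2, 3), t3=round(t3, 3))
    elif kind == "partial_B":
        fields.update(break_ns=round(rng.uniform(2.0, 8.0), 3))
    elif kind == "refold_A":
        fields.update(break_ns=round(rng.uniform(4.0, 8.0), 3),
                      refold_ns=round(rng.uniform(12.0, 17.0), 3))
    fields.update(overrides)
    return ScenarioScript(kind=kind, variant=variant, protonation=protonation,
                          seed=int(seed), **fields)


# ----------------------------------------------------------------------
# torsion-schedule machinery


def _target_array(name: str) -> np.ndarray:
    t = TARGETS[name]
    return np.array([t["phi"], t["psi"], t["chi1"], t["chi2"]], dtype=float)


def _ang_delta(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Shortest signed angular difference b - a in degrees."""
    return (b - a + 180.0) % 360.0 - 180.0


@dataclass(frozen=True)
class _Segment:
    t_start: float
    t_end: float
    frm: str
    to: str
    power: float = 1.0  # easing exponent for the blend parameter


def _schedule(script: ScenarioScript) -> list[_Segment]:
    """Way-point segments for a scenario; gaps hold the previous target."""
    segs: list[_Segment] = []
    if script.kind == "stable":
        return segs
    if script.kind in ("partial_B", "refold_A"):
        tb = script.break_ns
        segs.append(_Segment(tb, tb + 0.2, "helix", "partial"))
        if script.kind == "refold_A":
            tr = script.refold_ns
            segs.append(_Segment(tr, tr + 0.3, "partial", "helix"))
        return segs
    # complete_C: the cluster way-point holds for a plateau spanning t2 so
    # that boxcar smoothing does not erode the E_np-np minimum; the first
    # qualifying smoothed minimum then falls at the plateau entry, i.e. t2
    t1, t2, t3 = script.t1, script.t2, script.t3
    gap12 = t2 - t1
    pre = min(0.05, 0.4 * gap12)  # plateau starts just before t2
    post = 0.10                   # and extends just past it
    if gap12 >= 0.18:
        # sharp helix->open drop at t1, hold, then an eased plunge into the
        # cluster reaching full depth at the plateau entry
        d1 = min(0.06, 0.3 * gap12)
        w2 = min(0.25, gap12 - d1 - pre)
        segs.append(_Segment(t1, t1 + d1, "helix", "open"))
        segs.append(_Segment(t2 - pre - w2, t2 - pre, "open", "cluster",
                             power=2.0))
    else:
        # short gap: plunge straight from the helix
        segs.append(_Segment(t1, t2 - pre, "helix", "cluster", power=1.5))
    w2r = 0.15
    w3 = min(0.3, t3 - t2 - post - w2r - 0.05)
    segs.append(_Segment(t2 + post, t2 + post + w2r, "cluster", "open"))
    segs.append(_Segment(t3 - w3, t3, "open", "polar", power=2.0))
    segs.append(_Segment(t3, t3 + 0.4, "polar", "extended"))
    return segs


def _torsion_schedule(script: ScenarioScript, times_ns: np.ndarray) -> np.ndarray:
    """(n_frames, 4, 14) torsion tensor following the scenario's segments."""
    segs = _schedule(script)
    out = np.broadcast_to(_target_array("helix"), (len(times_ns), 4, 14)).copy()
    for seg in segs:
        frm, to = _target_array(seg.frm), _target_array(seg.to)
        lam = (times_ns - seg.t_start) / max(seg.t_end - seg.t_start, 1e-9)
        inside = (times_ns >= seg.t_start) & (times_ns < seg.t_end)
        after = times_ns >= seg.t_end
        lam = np.clip(lam, 0.0, 1.0) ** seg.power
        delta = _ang_delta(frm, to)
        blend = frm + lam[:, None, None] * delta
        out[inside] = blend[inside]
        out[after] = to
        current = to
    # wrap into (-180, 180]
    out = (out + 180.0) % 360.0 - 180.0
    out[out == -180.0] = 180.0
    return out


#: Correlation length (Å) of the thermal-jitter displacement field.
JITTER_CORR_LENGTH = 5.0


def _correlated_jitter(
    rng: np.random.Generator,
    coords: np.ndarray,
    amplitude: float,
    corr_length: float = JITTER_CORR_LENGTH,
    chunk: int = 200,
) -> np.ndarray:
    """Spatially correlated Gaussian displacement field.

    Thermal motion of a compact peptide is collective: covalently bonded and
    packed neighbours move together, so stiff short-range distances
    fluctuate far less than the per-atom amplitude.  Displacements are
    drawn per frame from a squared-exponential kernel over the clean
    coordinates; each atom's marginal RMS displacement equals ``amplitude``
    (per-coordinate σ = amplitude/√3).
    """
    if amplitude == 0.0:
        return np.zeros_like(coords)
    sigma = amplitude / np.sqrt(3.0)
    out = np.empty_like(coords)
    n = coords.shape[1]
    eye = 1e-8 * np.eye(n)

    # factorise the kernel once per *distinct* clean conformation: long
    # constant stretches (holds) share one Cholesky factor
    T = len(coords)
    change = np.ones(T, dtype=bool)
    change[1:] = np.any(coords[1:] != coords[:-1], axis=(1, 2))
    L = None
    starts = np.flatnonzero(change)
    bounds = np.append(starts, T)
    for s, e in zip(bounds[:-1], bounds[1:]):
        X = coords[s]
        d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
        L = np.linalg.cholesky(np.exp(-d2 / (2.0 * corr_length**2)) + eye)
        for lo in range(s, e, chunk):
            hi = min(lo + chunk, e)
            g = rng.standard_normal((hi - lo, n, 3))
            out[lo:hi] = sigma * np.einsum("ij,tjk->tik", L, g)
    return out


def generate_trajectory(
    script: ScenarioScript,
    topology: PeptideTopology | None = None,
) -> tuple[Trajectory, GroundTruth]:
    """Generate a synthetic trajectory and its ground truth.

    Frames are built from the scenario's torsion schedule and perturbed by
    seeded correlated Gaussian jitter whose per-atom RMS displacement
    equals ``script.jitter``.  The same script always yields bit-identical
    coordinates.
    """
    if topology is None:
        topology = build_topology(script.variant, script.protonation)
    n_frames = int(round(script.duration_ns * 1000.0 / script.stride_ps))
    times_ns = script.stride_ps * (np.arange(n_frames) + 1) / 1000.0
    tors = _torsion_schedule(script, times_ns)
    coords = build_frames(topology, tors[:, 0], tors[:, 1], tors[:, 2],
                          tors[:, 3])
    rng = np.random.default_rng([int(script.seed) % (2**31), 7])
    coords = coords + _correlated_jitter(rng, coords, script.jitter)
    traj = Trajectory(
        topology, coords, stride_ps=script.stride_ps,
        metadata={
            "kind": script.kind, "variant": script.variant,
            "protonation": script.protonation, "seed": str(script.seed),
            "temperature_k": str(script.temperature_k),
        },
    )
    truth = GroundTruth(script.kind, script.variant, script.protonation,
                        script.seed, script.intended_group,
                        script.t1, script.t2, script.t3)
    return traj, truth


# ----------------------------------------------------------------------
# shipped ensemble presets


def ensemble_spec(variant: str) -> list[str]:
    """Scenario kinds making up the shipped per-variant ensembles.

    The wild-type ensemble mixes all behaviours (7 A, 8 B, 5 C over 20
    trajectories); the helix-stabilised mutants never unfold completely
    (7 A, 3 B over 10 trajectories).
    """
    if variant == "WT":
        return (["stable"] * 4 + ["refold_A"] * 3 + ["partial_B"] * 8
                + ["complete_C"] * 5)
    if variant in ("MA", "ML"):
        return ["stable"] * 5 + ["refold_A"] * 2 + ["partial_B"] * 3
    raise ValueError(f"unknown variant {variant!r}")


def make_ensemble(
    variant: str,
    base_seed: int = 0,
    jitter: float = DEFAULT_JITTER,
) -> list[tuple[Trajectory, GroundTruth]]:
    """Generate the shipped ensemble for a variant (protonation alternates)."""
    out = []
    for i, kind in enumerate(ensemble_spec(variant)):
        seed = (int(base_seed) * 10007 + 131 * i + 17) % (2**31)
        script = make_scenario(kind, variant, "+" if i % 2 == 0 else "0",
                               seed=seed, jitter=jitter)
        out.append(generate_trajectory(script))
    return out
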