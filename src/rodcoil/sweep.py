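"""Parameter-sweep driver reproducing the morphology scans at any scale.

One simulation + analysis per swept value of eps_RR, L_R, L_C or phi, with
independent per-point seeds derived from a master seed by a splittable
scheme (``SeedSequence(master, spawn_key=(index,))``), so adding points
never reshuffles existing ones and a sweep table is a pure function of
(configuration, master seed).
"""

from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import ClassifierConfig, classify_morphology
from .integrator import RunParams, run
from .io import RunConfig, write_xyz
from .model import ChainSpec, ForceField, MixtureComposition

SWEEPABLE = ("eps_RR", "L_R", "L_C", "phi")


@dataclass
class SweepSpec:
    """What to sweep: parameter name, values, optional output directory."""

    param: str
    values: list[float]
    out_dir: str | Path | None = None
    overrides: dict = field(default_factory=dict)  # RunParams field overrides
    master_seed: int = 0
    save_frames: bool = False

    def __post_init__(self) -> None:
        if self.param not in SWEEPABLE:
            raise ValueError(f"swept parameter must be one of {SWEEPABLE}")
        if not self.values:
            raise ValueError("sweep value list is empty")


def point_seed(master_seed: int, index: int) -> int:
    """Independent per-point seed; stable under list extension."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2**31))


def _apply(param: str, value: float, comp: MixtureComposition, ff: ForceField):
    comp = dataclasses.replace(comp)
    ff = dataclasses.replace(ff)
    if param == "eps_RR":
        ff.eps_rr = float(value)
    elif param == "L_R":
        comp.copolymer = ChainSpec(
            int(round(value)), comp.copolymer.n_coil_beads
        )
    elif param == "L_C":
        comp.copolymer = ChainSpec(
            comp.copolymer.n_rod_beads, int(round(value))
        )
    elif param == "phi":
        comp.n_copolymers = int(round(value * comp.n_homopolymers))
    return comp, ff


def run_sweep(
    spec: SweepSpec,
    base: RunConfig,
    classifier: ClassifierConfig | None = None,
) -> pd.DataFrame:
    """Run one simulation + morphology analysis per swept value.

    Returns a table with one row per point (parameter value, morphology
    label, S, P1, P2, unimer fraction, cluster count, seed, wall time).
    Per-point failures are recorded in the ``error`` column and skipped,
    not fatal.  If ``spec.out_dir`` is set, the table is written there as
    ``sweep_<param>.tsv`` (plus final frames when ``save_frames``).
    """
    out_dir = Path(spec.out_dir) if spec.out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, value in enumerate(spec.values):
        seed = point_seed(spec.master_seed, i)
        row = {"param": spec.param, "value": float(value), "seed": seed}
        t0 = time.perf_counter()
        try:
            comp, ff = _apply(spec.param, value, base.composition, base.forcefield)
            params = replace(base.params, seed=seed, **spec.overrides)
            traj = run(comp, ff, params, box_length=base.box_length)
            # metrics from the final frame; the label by majority vote over
            # the production half of the snapshots (labels of coarsening
            # intermediates flicker frame to frame)
            rep = classify_morphology(traj.frame(traj.n_frames - 1), classifier)
            half = max(1, traj.n_frames // 2)
            tail = [
                classify_morphology(traj.frame(i), classifier).label
                for i in range(traj.n_frames - half, traj.n_frames)
            ]
            counts = {lab: tail.count(lab) for lab in set(tail)}
            best = max(counts.values())
            majority = [lab for lab in reversed(tail) if counts[lab] == best][0]
            row.update(
                label=majority,
                S=rep.order_parameter,
                P1=rep.p1_value,
                P2=rep.p2_value,
                unimer_fraction=rep.unimer_fraction,
                n_clusters=rep.n_clusters,
                error="",
            )
            if out_dir is not None and spec.save_frames:
                write_xyz(traj, out_dir / f"{spec.param}_{value:g}.xyz")
        except Exception as exc:  # per-point failures are recorded, not fatal
            row.update(
                label="error", S=np.nan, P1=np.nan, P2=np.nan,
                unimer_fraction=np.nan, n_clusters=0, error=str(exc),
            )
        row["wall_time_s"] = time.perf_counter() - t0
        rows.append(row)
    table = pd.DataFrame(rows)
    if out_dir is not None:
        table.to_csv(out_dir / f"sweep_{spec.param}.tsv", sep="\t", index=False)
    return table


__all__ = ["SweepSpec", "SWEEPABLE", "point_seed", "run_sweep"]
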