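"""Extended-XYZ trajectory I/O and TOML configuration loading.

Frame layout::

    <n_beads>
    step=<int> box=<L> topo=<groups>
    R <x> <y> <z>
    ...

Labels are R (copolymer rod bead), C (copolymer coil bead), H (homopolymer
bead).  Coordinates are written with 17 significant digits, so a write/read
round trip is bit-exact for float64.  The optional ``topo`` token is a
run-length encoding of the chain list (``<count>x<rod>+<coil>`` groups,
comma separated, e.g. ``4x150+0,660x7+3``); when present, chain identities
are reconstructed exactly.  Without it, chains are inferred from species
runs (adjacent homopolymers cannot be told apart in that case).
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .integrator import RunParams, Trajectory
from .model import (
    LABEL_SPECIES,
    SPECIES_COIL,
    SPECIES_HOMO,
    SPECIES_LABELS,
    ChainSpec,
    ForceField,
    MixtureComposition,
    SystemState,
    build_topology,
)


class XYZFormatError(ValueError):
    """Malformed extended-XYZ input; the message carries the line number."""


def _topo_token(state: SystemState) -> str:
    groups: list[tuple[int, int, int]] = []  # (count, n_rod, n_coil)
    for start in _chain_starts(state.chain_id):
        sl = state.species[start[0] : start[1]]
        n_coil = int(np.sum(sl == SPECIES_COIL))
        n_rod = len(sl) - n_coil
        if groups and groups[-1][1] == n_rod and groups[-1][2] == n_coil:
            groups[-1] = (groups[-1][0] + 1, n_rod, n_coil)
        else:
            groups.append((1, n_rod, n_coil))
    return ",".join(f"{c}x{r}+{n}" for c, r, n in groups)


def _chain_starts(chain_id: np.ndarray) -> list[tuple[int, int]]:
    boundaries = np.flatnonzero(np.diff(chain_id)) + 1
    edges = np.concatenate(([0], boundaries, [len(chain_id)]))
    return list(zip(edges[:-1], edges[1:]))


def _parse_topo(token: str) -> list[ChainSpec]:
    chains = []
    for group in token.split(","):
        count, rest = group.split("x")
        rod, coil = rest.split("+")
        chains.extend([ChainSpec(int(rod), int(coil))] * int(count))
    return chains


def _infer_chains(species: np.ndarray) -> list[ChainSpec]:
    """Fallback chain inference from species runs (see module docstring)."""
    chains = []
    i = 0
    n = len(species)
    while i < n:
        if species[i] == SPECIES_HOMO:
            j = i
            while j < n and species[j] == SPECIES_HOMO:
                j += 1
            chains.append(ChainSpec(j - i, 0))
            i = j
        else:
            j = i
            while j < n and species[j] == LABEL_SPECIES["R"]:
                j += 1
            k = j
            while k < n and species[k] == SPECIES_COIL:
                k += 1
            chains.append(ChainSpec(j - i, k - j))
            i = k
    return chains


def write_xyz(traj_or_state: Trajectory | SystemState, path: str | Path) -> None:
    """Write a trajectory (or a single frame) as extended XYZ."""
    if isinstance(traj_or_state, SystemState):
        state = traj_or_state
        traj = Trajectory(template=state)
        traj.append(0, state.positions)
    else:
        traj = traj_or_state
    template = traj.template
    topo = _topo_token(template)
    labels = [SPECIES_LABELS[int(s)] for s in template.species]
    with open(path, "w") as fh:
        for step, pos in zip(traj.steps, traj.positions):
            fh.write(f"{len(pos)}\n")
            fh.write(f"step={step} box={traj.box_length!r} topo={topo}\n")
            for lab, (x, y, z) in zip(labels, pos):
                fh.write(f"{lab} {x:.17g} {y:.17g} {z:.17g}\n")


def read_xyz(path: str | Path) -> Trajectory:
    """Read an extended-XYZ trajectory written by :func:`write_xyz`.

    Raises :class:`XYZFormatError` (with the offending line number) on a
    malformed count line, an unknown species label, or a box mismatch
    between frames.
    """
    frames: list[tuple[int, np.ndarray, np.ndarray]] = []
    box: float | None = None
    topo_token: str | None = None
    with open(path) as fh:
        lines = fh.readlines()
    ln = 0
    n_lines = len(lines)
    frame_index = 0
    while ln < n_lines:
        if not lines[ln].strip():
            ln += 1
            continue
        try:
            count = int(lines[ln].strip())
        except ValueError:
            raise XYZFormatError(f"line {ln + 1}: expected a bead count") from None
        if ln + 1 >= n_lines:
            raise XYZFormatError(f"line {ln + 2}: missing comment line")
        step = frame_index
        frame_box = None
        for token in lines[ln + 1].split():
            if token.startswith("step="):
                step = int(token[5:])
            elif token.startswith("box="):
                frame_box = float(token[4:])
            elif token.startswith("topo="):
                topo_token = token[5:]
        if frame_box is None:
            raise XYZFormatError(f"line {ln + 2}: comment line lacks box=")
        if box is None:
            box = frame_box
        elif frame_box != box:
            raise XYZFormatError(
                f"line {ln + 2}: box {frame_box} differs from first frame ({box})"
            )
        if ln + 2 + count > n_lines:
            raise XYZFormatError(
                f"line {ln + 1}: count {count} exceeds remaining lines"
            )
        species = np.empty(count, dtype=np.int64)
        pos = np.empty((count, 3))
        for k in range(count):
            parts = lines[ln + 2 + k].split()
            if len(parts) != 4:
                raise XYZFormatError(
                    f"line {ln + 3 + k}: expected 'LABEL x y z', got {len(parts)} fields"
                )
            if parts[0] not in LABEL_SPECIES:
                raise XYZFormatError(
                    f"line {ln + 3 + k}: unknown species label {parts[0]!r}"
                )
            species[k] = LABEL_SPECIES[parts[0]]
            pos[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
        if ln + 2 + count < n_lines:
            nxt = lines[ln + 2 + count].strip()
            if nxt and not nxt.isdigit():
                raise XYZFormatError(
                    f"line {ln + 1}: count {count} does not match atom rows"
                )
        frames.append((step, species, pos))
        ln += 2 + count
        frame_index += 1
    if not frames:
        raise XYZFormatError("file contains no frames")
    _, species0, pos0 = frames[0]
    chains = _parse_topo(topo_token) if topo_token else _infer_chains(species0)
    species, chain_id, topo = build_topology(chains)
    if not np.array_equal(species, species0):
        raise XYZFormatError("topo token inconsistent with species labels")
    template = SystemState(
        pos0.copy(), np.zeros_like(pos0), species, chain_id, box, topo
    )
    traj = Trajectory(template=template, metadata={"source": str(path)})
    for step, sp, pos in frames:
        if not np.array_equal(sp, species0):
            raise XYZFormatError("species labels change between frames")
        traj.append(step, pos)
    return traj


# ---------------------------------------------------------------------------
# configuration files


@dataclass
class RunConfig:
    """Fully resolved configuration of one simulation run."""

    composition: MixtureComposition
    forcefield: ForceField
    params: RunParams
    box_length: float


def load_config(path: str | Path) -> RunConfig:
    """Load a TOML run configuration.

    Sections ``[composition]``, ``[forcefield]`` and ``[run]``; every key is
    optional and defaults to the production values (R7C3/R150 mixture,
    eps_RR = 2.1, box 150, dt = 0.004, T = 3.0).
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    comp_d = dict(raw.get("composition", {}))
    ff_d = dict(raw.get("forcefield", {}))
    run_d = dict(raw.get("run", {}))
    comp = MixtureComposition(
        n_copolymers=int(comp_d.pop("n_copolymers", 660)),
        copolymer=ChainSpec(
            int(comp_d.pop("rod_beads", 7)), int(comp_d.pop("coil_beads", 3))
        ),
        homopolymer=ChainSpec(int(comp_d.pop("homopolymer_beads", 150))),
        n_homopolymers=int(comp_d.pop("n_homopolymers", 4)),
    )
    box_length = float(comp_d.pop("box_length", run_d.pop("box_length", 150.0)))
    if comp_d:
        raise ValueError(f"unknown [composition] keys: {sorted(comp_d)}")
    ff = ForceField(**ff_d)
    params = RunParams(**run_d)
    return RunConfig(comp, ff, params, box_length)


__all__ = [
    "XYZFormatError",
    "RunConfig",
    "write_xyz",
    "read_xyz",
    "load_config",
    "config_from_dict",
]
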