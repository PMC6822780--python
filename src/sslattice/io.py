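"""Configuration parsing, trajectory and results I/O.

Configurations are TOML; trajectories are a bespoke plain-text frame format
(no standard lattice-polymer interchange format exists):

    #FRAME <step> <L> <n_beads>
    <bead_id> <chain_id> <mol_type> <bead_type> <x> <y> <z> <partner_id>

with 0-based integer coordinates in [0, L) and partner_id = -1 for unbound.
Round trips are exact.  Result tables are TSV; every run writes a JSON
manifest (config digest, seeds, outputs).
"""

from __future__ import annotations

import hashlib
import json
import tomllib

from pathlib import Path

import numpy as np

from .architecture import BeadType, build_architecture
from .energy import EnergyModel
from .fixtures import build_fixture
from .lattice import LatticeConfig
from .mc import MoveSchedule, RunConfig, Trajectory
from .system import LatticeSystem

__all__ = ["parse_config", "emit_fixture_config", "write_trajectory",
           "read_trajectory", "write_move_stats", "RunManifest",
           "ConfigError"]


class ConfigError(ValueError):
    """Schema violation in a configuration file, with a field-level message."""


_TOP_KEYS = {"lattice", "bead_types", "molecules", "energy", "moves", "run"}
_MOVE_KEYS = {"cluster_translation", "chain_translation", "rotation", "local",
              "reptation", "double_pivot"}
_RUN_KEYS = {"steps", "equilibration", "sample_every", "seed", "replicas",
             "debug_check_every", "strict_double_pivot", "temperatures"}


def parse_config(path):
    """Parse and validate a TOML configuration.

    Returns (system, schedule, run_config, temperatures).  Unknown keys are
    rejected; omitting [moves] applies the fixture family's published
    defaults when a ``fixture`` hint is present, else the generic defaults.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    unknown = set(raw) - _TOP_KEYS - {"fixture"}
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    for key in ("lattice", "molecules", "energy", "run"):
        if key not in raw:
            raise ConfigError(f"missing required section [{key}]")

    lat = raw["lattice"]
    if "L" not in lat:
        raise ConfigError("[lattice] requires integer L")
    lattice = LatticeConfig(int(lat["L"]))

    types = [BeadType(t["label"], bool(t["is_sticker"]))
             for t in raw.get("bead_types", [])]
    if not types:
        raise ConfigError("need at least one [[bead_types]] entry")

    molecules = []
    for m in raw["molecules"]:
        for req in ("name", "count", "beads", "bonds"):
            if req not in m:
                raise ConfigError(f"[[molecules]] entry missing {req!r}")
        arch = build_architecture(m["name"], m["beads"],
                                  [tuple(b) for b in m["bonds"]])
        molecules.append((arch, int(m["count"])))

    en = raw["energy"]
    pairs = {}
    for row in en.get("pairs", []):
        a, b, e = row
        k = (str(a), str(b))
        kc = tuple(sorted(k))
        if kc in pairs and pairs[kc] != float(e):
            raise ConfigError(f"asymmetric eps for pair {kc}")
        pairs[kc] = float(e)
    energy = EnergyModel(pairs, float(en.get("temperature", 1.0)),
                         en.get("reference_energy"))

    if "moves" in raw:
        mv = raw["moves"]
        unknown = set(mv) - _MOVE_KEYS
        if unknown:
            raise ConfigError(f"unknown [moves] keys: {sorted(unknown)}")
        schedule = MoveSchedule(**{k: float(v) for k, v in mv.items()})
    elif "fixture" in raw:
        schedule = build_fixture(raw["fixture"]).schedule
    else:
        schedule = MoveSchedule()

    rn = dict(raw["run"])
    unknown = set(rn) - _RUN_KEYS
    if unknown:
        raise ConfigError(f"unknown [run] keys: {sorted(unknown)}")
    temperatures = rn.pop("temperatures", None)
    if "steps" not in rn:
        raise ConfigError("[run] requires steps")
    run = RunConfig(schedule=schedule, **{k: (bool(v) if k == "strict_double_pivot"
                                              else int(v)) for k, v in rn.items()})
    system = LatticeSystem(lattice, types, molecules, energy)
    return system, schedule, run, temperatures


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    return repr(v)


def emit_fixture_config(name: str, path, *, L: int, counts: dict[str, int],
                        run: RunConfig | None = None,
                        tstar: float | None = None) -> None:
    """Write a ready-to-run TOML configuration for a named fixture."""
    fx = build_fixture(name, tstar=tstar)
    run = run or RunConfig(fx.schedule, steps=1_000_000, equilibration=100_000,
                           sample_every=50_000, seed=1)
    lines = [f"fixture = {json.dumps(name)}", "", "[lattice]", f"L = {L}", ""]
    for t in fx.bead_types:
        lines += ["[[bead_types]]", f"label = {json.dumps(t.label)}",
                  f"is_sticker = {_toml_value(t.is_sticker)}", ""]
    for arch in fx.architectures:
        lines += ["[[molecules]]", f"name = {json.dumps(arch.name)}",
                  f"count = {counts.get(arch.name, 0)}",
                  f"beads = {_toml_value(list(arch.beads))}",
                  f"bonds = {_toml_value([list(b) for b in arch.bonds])}", ""]
    lines += ["[energy]",
              f"pairs = {_toml_value([[a, b, e] for (a, b), e in fx.energy.pairs.items()])}",
              f"temperature = {_toml_value(float(fx.energy.temperature))}"]
    if fx.energy.reference_energy is not None:
        lines.append(f"reference_energy = {_toml_value(float(fx.energy.reference_energy))}")
    s = fx.schedule
    lines += ["", "[moves]"]
    for k in ("cluster_translation", "chain_translation", "rotation", "local",
              "reptation", "double_pivot"):
        lines.append(f"{k} = {_toml_value(float(getattr(s, k)))}")
    lines += ["", "[run]", f"steps = {run.steps}",
              f"equilibration = {run.equilibration}",
              f"sample_every = {run.sample_every}", f"seed = {run.seed}",
              f"replicas = {run.replicas}",
              f"debug_check_every = {run.debug_check_every}", ""]
    Path(path).write_text("\n".join(lines))


# ----------------------------------------------------------------------
# trajectories
# ----------------------------------------------------------------------

def write_trajectory(traj: Trajectory, path) -> None:
    s = traj.system
    L = s.lattice.L
    with open(path, "w") as fh:
        for i in range(traj.n_snapshots):
            fh.write(f"#FRAME {traj.steps[i]} {L} {s.n_beads}\n")
            for b in range(s.n_beads):
                x, y, z = traj.pos[i, b]
                fh.write(f"{b} {s.chain_of[b]} {s.chain_mt[s.chain_of[b]]} "
                         f"{s.btype[b]} {x} {y} {z} {traj.partner[i, b]}\n")


def read_trajectory(path, system: LatticeSystem) -> Trajectory:
    """Parse the frame format back; validates counts and partner symmetry."""
    steps, poss, parts = [], [], []
    with open(path) as fh:
        lineno = 0
        frame_pos = frame_part = None
        expected = 0
        seen = 0
        for line in fh:
            lineno += 1
            line = line.strip()
            if not line:
                continue
            if line.startswith("#FRAME"):
                if frame_pos is not None and seen != expected:
                    raise ValueError(f"line {lineno}: truncated frame")
                parts_hdr = line.split()
                if len(parts_hdr) != 4:
                    raise ValueError(f"line {lineno}: malformed frame header")
                step, L, n = int(parts_hdr[1]), int(parts_hdr[2]), int(parts_hdr[3])
                if L != system.lattice.L or n != system.n_beads:
                    raise ValueError(f"line {lineno}: frame does not match system")
                steps.append(step)
                frame_pos = np.zeros((n, 3), dtype=np.int64)
                frame_part = np.full(n, -1, dtype=np.int64)
                poss.append(frame_pos)
                parts.append(frame_part)
                expected, seen = n, 0
                continue
            f = line.split()
            if len(f) != 8 or frame_pos is None:
                raise ValueError(f"line {lineno}: malformed bead row")
            b = int(f[0])
            frame_pos[b] = (int(f[4]), int(f[5]), int(f[6]))
            frame_part[b] = int(f[7])
            seen += 1
        if frame_pos is not None and seen != expected:
            raise ValueError("truncated final frame")
    for fp in parts:  # partner symmetry check
        for u, v in enumerate(fp):
            if v >= 0 and fp[v] != u:
                raise ValueError(f"partner map not symmetric: {u} -> {v}")
    if not steps:
        return Trajectory(system, np.zeros(0, dtype=np.int64),
                          np.zeros((0, system.n_beads, 3), dtype=np.int64),
                          np.zeros((0, system.n_beads), dtype=np.int64))
    return Trajectory(system, steps, np.stack(poss), np.stack(parts))


def write_move_stats(stats, path) -> None:
    stats.to_frame().to_csv(path, sep="\t", index=False)


class RunManifest:
    """Provenance record for one run: config digest, seeds, output files."""

    def __init__(self, config_path, seed, outputs, extra=None):
        text = Path(config_path).read_bytes() if config_path else b""
        self.data = {
            "config": str(config_path),
            "config_sha256": hashlib.sha256(text).hexdigest(),
            "seed": seed,
            "outputs": [str(o) for o in outputs],
        }
        if extra:
            self.data.update(extra)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.data, indent=2) + "\n")
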