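"""File formats: XYZ trajectories, YAML topologies/configs, minimal PDB.

Trajectory frames are XYZ blocks whose comment line carries ``key=value``
metadata (``time`` in ps, ``radius`` in Å).  The topology schema is a YAML
document with ``atoms`` (element, mass, charge, sigma, epsilon, molecule),
plus optional ``rigid_bodies``, ``virtual_sites``, ``constraints`` and
``frozen`` sections.
"""

import numpy as np
import yaml

from .dynamics import SimulationConfig
from .forcefield import RigidBody, Topology, VirtualSite

__all__ = [
    "write_xyz", "read_xyz", "write_topology", "read_topology",
    "load_config", "write_pdb", "read_pdb",
]


# ---------------------------------------------------------------------------
# XYZ

def write_xyz(path, frames, elements, mode="w"):
    """Write frames as (time, radius, positions) XYZ blocks."""
    with open(path, mode) as fh:
        for time, radius, pos in frames:
            fh.write(f"{len(pos)}\n")
            fh.write(f"time={time:.6f} radius={radius:.6f}\n")
            for el, (x, y, z) in zip(elements, pos):
                fh.write(f"{el:<2s} {x:18.10f} {y:18.10f} {z:18.10f}\n")


def read_xyz(path):
    """Read an XYZ trajectory; returns (frames, elements)."""
    frames = []
    elements = None
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            n = int(header)
            meta = {}
            for item in fh.readline().split():
                if "=" in item:
                    key, val = item.split("=", 1)
                    meta[key] = float(val)
            els, pos = [], np.empty((n, 3))
            for i in range(n):
                parts = fh.readline().split()
                els.append(parts[0])
                pos[i] = [float(p) for p in parts[1:4]]
            elements = els
            frames.append((meta.get("time", 0.0), meta.get("radius", 0.0), pos))
    return frames, elements


# ---------------------------------------------------------------------------
# topology

def write_topology(path, topo: Topology):
    doc = {
        "atoms": [
            {"element": topo.elements[i] if topo.elements else "X",
             "mass": float(topo.masses[i]), "charge": float(topo.charges[i]),
             "sigma": float(topo.lj_sigma[i]),
             "epsilon": float(topo.lj_epsilon[i]),
             "molecule": int(topo.molecule[i])}
            for i in range(topo.n_atoms)
        ],
        "rigid_bodies": [np.asarray(b.atoms).tolist()
                         for b in topo.rigid_bodies],
        "virtual_sites": [
            {"site": int(vs.site), "parents": list(map(int, vs.parents)),
             "a": float(vs.a), "b": float(vs.b), "c": float(vs.c)}
            for vs in topo.virtual_sites
        ],
        "constraints": [[int(i), int(j), float(d)]
                        for i, j, d in topo.constraints],
        "frozen": np.flatnonzero(topo.frozen).tolist(),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_topology(path) -> Topology:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    atoms = doc["atoms"]
    n = len(atoms)
    frozen = np.zeros(n, dtype=bool)
    frozen[doc.get("frozen", [])] = True
    return Topology(
        masses=np.array([a["mass"] for a in atoms], dtype=float),
        charges=np.array([a["charge"] for a in atoms], dtype=float),
        lj_sigma=np.array([a.get("sigma", 0.0) for a in atoms], dtype=float),
        lj_epsilon=np.array([a.get("epsilon", 0.0) for a in atoms], dtype=float),
        molecule=np.array([a["molecule"] for a in atoms], dtype=int),
        elements=[a.get("element", "X") for a in atoms],
        rigid_bodies=[RigidBody(atoms=np.asarray(b, dtype=int))
                      for b in doc.get("rigid_bodies", [])],
        virtual_sites=[VirtualSite(site=v["site"],
                                   parents=tuple(v["parents"]),
                                   a=v.get("a", 0.0), b=v.get("b", 0.0),
                                   c=v.get("c", 0.0))
                       for v in doc.get("virtual_sites", [])],
        constraints=[(int(i), int(j), float(d))
                     for i, j, d in doc.get("constraints", [])],
        frozen=frozen,
    )


# ---------------------------------------------------------------------------
# config

def load_config(path) -> SimulationConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return SimulationConfig(**doc)


# ---------------------------------------------------------------------------
# minimal PDB

def write_pdb(path, positions, elements, molecule=None):
    """Single-model minimal PDB (HETATM records, element right-justified)."""
    with open(path, "w") as fh:
        for i, (el, (x, y, z)) in enumerate(zip(elements, positions), 1):
            res = 1 if molecule is None else int(molecule[i - 1]) + 1
            fh.write(
                f"HETATM{i:5d} {el:<4s}MOL {'A'}{res % 10000:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {el:>2s}\n")
        fh.write("END\n")


def read_pdb(path):
    """Read coordinates and elements from ATOM/HETATM records."""
    els, pos = [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("ATOM", "HETATM")):
                pos.append([float(line[30:38]), float(line[38:46]),
                            float(line[46:54])])
                el = line[76:78].strip() or line[12:16].strip()[:1]
                els.append(el)
    return np.asarray(pos), els
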