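"""Atomic models: a point cloud of weighted atoms with an identifier.

Models are read from PDB or mmCIF files through gemmi.  Only element,
position and an optional per-atom weight are retained — rigid-body density
docking needs nothing else.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import gemmi
import numpy as np


class ModelFormatError(ValueError):
    """A structure file could not be parsed into at least one atom."""


@dataclasses.dataclass
class AtomicModel:
    """A set of atoms (element, position in Å, positive weight) with an id."""

    model_id: str
    elements: list[str]
    positions: np.ndarray  # (n, 3) Å
    weights: np.ndarray | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n, 3)")
        n = self.positions.shape[0]
        if n < 1:
            raise ValueError("model must contain at least one atom")
        if not np.isfinite(self.positions).all():
            raise ValueError("atom positions must be finite")
        if len(self.elements) != n:
            raise ValueError("elements/positions length mismatch")
        if self.weights is None:
            self.weights = np.ones(n)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.shape != (n,):
            raise ValueError("weights must have shape (n,)")
        if not (np.isfinite(self.weights).all() and (self.weights > 0).all()):
            raise ValueError("weights must be finite and positive")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    @property
    def centroid(self) -> np.ndarray:
        """Unweighted mean of atom positions (Å)."""
        return self.positions.mean(axis=0)

    @property
    def radius(self) -> float:
        """Bounding-sphere radius about the centroid (Å)."""
        d = self.positions - self.centroid
        return float(np.sqrt((d * d).sum(axis=1).max()))

    def element_masses(self) -> np.ndarray:
        """Standard atomic masses (u) looked up per element symbol."""
        return np.array(
            [gemmi.Element(el).weight for el in self.elements], dtype=float
        )

    def transformed(self, rotation: np.ndarray,
                    translation: np.ndarray) -> "AtomicModel":
        """Rotate about the centroid, then translate (both in Å)."""
        R = np.asarray(rotation, dtype=float).reshape(3, 3)
        t = np.asarray(translation, dtype=float).reshape(3)
        c = self.centroid
        pos = (self.positions - c) @ R.T + c + t
        return AtomicModel(self.model_id, list(self.elements), pos,
                           self.weights.copy())

    def mirrored(self) -> "AtomicModel":
        """Reflect through the plane x = centroid_x (improper image)."""
        c = self.centroid
        pos = self.positions.copy()
        pos[:, 0] = 2.0 * c[0] - pos[:, 0]
        return AtomicModel(self.model_id, list(self.elements), pos,
                           self.weights.copy())


def read_model(path, weight_mode: str = "unit") -> AtomicModel:
    """Read a PDB or mmCIF file as one :class:`AtomicModel`.

    ATOM and HETATM records of the first model, all chains, are used.  The
    model id defaults to the filename stem.  ``weight_mode`` is ``unit``
    (default, weight 1.0 per atom) or ``element-mass``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ModelFormatError(f"no atoms parsed from {path} (empty file)")
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Detect)
    except (RuntimeError, ValueError, OSError) as exc:
        raise ModelFormatError(f"unreadable structure file {path}: {exc}") from exc
    elements, positions = [], []
    if len(st) > 0:
        for chain in st[0]:
            for residue in chain:
                for atom in residue:
                    elements.append(atom.element.name)
                    positions.append([atom.pos.x, atom.pos.y, atom.pos.z])
    if not positions:
        raise ModelFormatError(f"no atoms parsed from {path}")
    model = AtomicModel(path.stem, elements, np.array(positions))
    if weight_mode == "element-mass":
        model.weights = model.element_masses()
    elif weight_mode != "unit":
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    return model


def write_model(model: AtomicModel, path) -> None:
    """Write a model as a minimal PDB file (one atom per UNK residue).

    PDB coordinates carry three decimals, so positions round-trip to 1e-3 Å.
    """
    st = gemmi.Structure()
    st.name = model.model_id
    md = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for i in range(model.n_atoms):
        res = gemmi.Residue()
        res.name = "UNK"
        res.seqid = gemmi.SeqId(i + 1, " ")
        atom = gemmi.Atom()
        el = model.elements[i]
        atom.name = el
        atom.element = gemmi.Element(el)
        x, y, z = model.positions[i]
        atom.pos = gemmi.Position(x, y, z)
        atom.occ = 1.0
        res.add_atom(atom)
        chain.add_residue(res)
    md.add_chain(chain)
    st.add_model(md)
    st.setup_entities()
    st.write_pdb(str(path))
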