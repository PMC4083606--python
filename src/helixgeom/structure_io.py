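"""Reading Cα helix traces from multi-model PDB files.

A trajectory is stored as one ``MODEL``/``ENDMDL`` block per frame. The user
names each helix by chain and an inclusive author-numbered residue range
(conventionally labelled ``G-ALPHA1`` and ``G-ALPHA2`` for the two helices
flanking the MHC class I peptide-binding groove); this module extracts the
ordered Cα coordinates of those residues for every frame.

Helix ranges are fixed, user-supplied input and constant across frames —
per-frame secondary-structure reclassification would change the spline
support length between frames and is deliberately not done.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

from .errors import StructureError, ValidationError

__all__ = ["HelixTrace", "HelixSelection", "read_frames", "load_selections"]

#: minimum trace length: a degree-2 fit needs at least 4 points to leave
#: residual degrees of freedom
MIN_TRACE_POINTS = 4


@dataclass(frozen=True)
class HelixTrace:
    """Ordered Cα coordinates of one helix in one trajectory frame.

    ``residue_ids`` are strictly increasing author numbers; ``coords`` is an
    ``(n, 3)`` float array in Å, one row per residue in sequence order.
    """

    frame_index: int
    chain_id: str
    residue_ids: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        rid = np.asarray(self.residue_ids, dtype=int)
        xyz = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "residue_ids", rid)
        object.__setattr__(self, "coords", xyz)
        if xyz.ndim != 2 or xyz.shape[1] != 3:
            raise ValidationError(f"coords must be (n, 3), got {xyz.shape}")
        if len(rid) != len(xyz):
            raise ValidationError(
                f"residue_ids ({len(rid)}) and coords ({len(xyz)}) lengths differ"
            )
        if len(xyz) < MIN_TRACE_POINTS:
            raise ValidationError(
                f"coords: need at least {MIN_TRACE_POINTS} residues, got {len(xyz)}"
            )
        if np.any(np.diff(rid) <= 0):
            raise ValidationError("residue_ids: must be strictly increasing")
        if not np.all(np.isfinite(xyz)):
            raise ValidationError("coords: non-finite coordinate")

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)


@dataclass(frozen=True)
class HelixSelection:
    """One helix: chain + inclusive author-numbered residue range."""

    chain_id: str
    first_residue: int
    last_residue: int
    label: str = "other"

    def __post_init__(self) -> None:
        if self.first_residue >= self.last_residue:
            raise ValidationError(
                f"first_residue ({self.first_residue}) must be < "
                f"last_residue ({self.last_residue})"
            )


def _ca_coordinate(residue, frame: int, sel: HelixSelection, resnum: int) -> np.ndarray:
    if "CA" not in residue:
        raise StructureError(
            f"frame {frame}: chain {sel.chain_id} residue {resnum} has no CA atom"
        )
    atom = residue["CA"]
    if atom.is_disordered():
        # keep altloc blank or 'A', ignore the rest
        chosen = None
        for alt in atom.disordered_get_id_list():
            if alt in ("", " ", "A"):
                chosen = atom.disordered_get(alt)
                break
        if chosen is None:
            raise StructureError(
                f"frame {frame}: chain {sel.chain_id} residue {resnum} CA has "
                f"only altlocs {atom.disordered_get_id_list()}"
            )
        atom = chosen
    return np.asarray(atom.get_coord(), dtype=float)


def _extract_trace(model, frame: int, sel: HelixSelection) -> HelixTrace:
    if sel.chain_id not in model:
        raise StructureError(f"frame {frame}: chain {sel.chain_id} not present")
    chain = model[sel.chain_id]

    by_number: dict[int, object] = {}
    for residue in chain:
        hetflag, resnum, icode = residue.get_id()
        if hetflag.strip():
            continue
        if sel.first_residue <= resnum <= sel.last_residue:
            if icode.strip():
                raise StructureError(
                    f"frame {frame}: chain {sel.chain_id} residue {resnum}{icode} "
                    f"carries an insertion code; insertion codes are not supported"
                )
            by_number[resnum] = residue

    residue_ids, coords = [], []
    for resnum in range(sel.first_residue, sel.last_residue + 1):
        if resnum not in by_number:
            raise StructureError(
                f"frame {frame}: chain {sel.chain_id} residue {resnum} "
                f"not found (selection {sel.label})"
            )
        residue_ids.append(resnum)
        coords.append(_ca_coordinate(by_number[resnum], frame, sel, resnum))
    return HelixTrace(
        frame_index=frame,
        chain_id=sel.chain_id,
        residue_ids=np.array(residue_ids),
        coords=np.array(coords),
    )


def read_frames(
    path: str | Path, selections: Sequence[HelixSelection]
) -> list[tuple[HelixTrace, ...]]:
    """Read a (multi-model) PDB file and extract one Cα trace per selection per frame.

    Returns a list with one tuple of :class:`HelixTrace` per ``MODEL``, in
    MODEL order (``frame_index`` is 0-based); a file without MODEL records
    yields a single frame. ATOM records with an altloc other than blank or
    ``'A'`` are ignored.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    if not selections:
        raise ValidationError("selections: at least one helix selection required")
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        try:
            structure = parser.get_structure(path.stem, str(path))
        except Exception as exc:  # Bio.PDB raises assorted exception types
            raise StructureError(f"could not parse {path}: {exc}") from exc
    models = list(structure)
    if not models:
        raise StructureError(f"{path}: no models found")
    frames = []
    for frame, model in enumerate(models):
        frames.append(tuple(_extract_trace(model, frame, sel) for sel in selections))
    return frames


def load_selections(path: str | Path) -> list[HelixSelection]:
    """Load helix selections from a YAML config.

    Expected layout::

        helices:
          G-ALPHA1: {chain: A, first_residue: 1, last_residue: 36}
          G-ALPHA2: {chain: B, first_residue: 1, last_residue: 36}
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "helices" not in data:
        raise ValidationError(f"{path}: config must contain a 'helices' mapping")
    selections = []
    for label, entry in data["helices"].items():
        try:
            selections.append(
                HelixSelection(
                    chain_id=str(entry["chain"]),
                    first_residue=int(entry["first_residue"]),
                    last_residue=int(entry["last_residue"]),
                    label=str(label),
                )
            )
        except KeyError as exc:
            raise ValidationError(f"{path}: helix {label!r} missing key {exc}") from exc
    return selections
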