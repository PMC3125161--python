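"""Read PDB files, reduce chains to Cα traces, and assign secondary structure.

A structure is represented by its ordered Cα sites only.  Secondary-structure
labels (H = helix, E = strand, C = coil/none) may come from a Cα-only
geometric assignment, from HELIX/SHEET records of the source file, or be
supplied directly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser

logger = logging.getLogger(__name__)

SSE_LABELS = frozenset("HEC")

# Cα-only window-distance acceptance bands (Å), in the style of P-SEA:
# d(i,i+2), d(i,i+3), d(i,i+4) for helix; d(i,i+2), d(i,i+3) for strand.
_HELIX_D2 = (5.0, 6.1)
_HELIX_D3 = (4.6, 5.8)
_HELIX_D4 = (5.7, 7.0)
_STRAND_D2 = (6.3, 7.2)
_STRAND_D3 = (9.0, 10.8)
_MIN_HELIX_RUN = 4
_MIN_STRAND_RUN = 3


class StructureError(ValueError):
    """Raised for unreadable or empty structure selections."""


class EmptyStructureError(StructureError):
    """Raised when the selected chain contains no Cα atoms."""


@dataclass(frozen=True)
class CAStructure:
    """An ordered Cα trace with per-site metadata.

    Attributes
    ----------
    id : str
        Identifier of the structure (file stem plus chain id for PDB input).
    coords : (n, 3) ndarray
        Cα coordinates in Å, in chain order.
    residue_ids : tuple of str
        Author residue numbering (with insertion codes) per site.
    sse : str or None
        Per-site labels in {H, E, C}; ``None`` until assigned.
    helix_ranges, sheet_ranges : tuple
        (chain, first_resseq, last_resseq) triples retained from
        HELIX/SHEET records, used by record-based SSE assignment.
    """

    id: str
    coords: np.ndarray
    residue_ids: tuple[str, ...]
    sse: str | None = None
    helix_ranges: tuple[tuple[str, int, int], ...] = field(default=())
    sheet_ranges: tuple[tuple[str, int, int], ...] = field(default=())
    chain: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 1:
            raise StructureError("coords must be a non-empty (n, 3) array")
        if not np.all(np.isfinite(coords)):
            raise StructureError("coordinates must be finite")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "residue_ids", tuple(str(r) for r in self.residue_ids))
        if len(self.residue_ids) != len(coords):
            raise StructureError("residue_ids length mismatch")
        if self.sse is not None:
            if len(self.sse) != len(coords):
                raise StructureError("sse label string length mismatch")
            if not set(self.sse) <= SSE_LABELS:
                raise StructureError(f"sse labels must be in {sorted(SSE_LABELS)}")

    def __len__(self) -> int:
        return self.coords.shape[0]

    def with_coords(self, coords: np.ndarray) -> "CAStructure":
        return replace(self, coords=np.asarray(coords, dtype=float))

    def slice(self, start: int, stop: int, new_id: str | None = None) -> "CAStructure":
        """Contiguous sub-structure on 0-based half-open [start, stop)."""
        if not (0 <= start < stop <= len(self)):
            raise StructureError(f"bad slice [{start}, {stop}) for length {len(self)}")
        return replace(
            self,
            id=new_id if new_id is not None else f"{self.id}[{start}:{stop}]",
            coords=self.coords[start:stop].copy(),
            residue_ids=self.residue_ids[start:stop],
            sse=self.sse[start:stop] if self.sse is not None else None,
        )


def _parse_sse_records(path: Path) -> tuple[list, list]:
    helices, sheets = [], []
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            try:
                if rec == "HELIX ":
                    helices.append((line[19].strip(), int(line[21:25]), int(line[33:37])))
                elif rec == "SHEET ":
                    sheets.append((line[21].strip(), int(line[22:26]), int(line[33:37])))
            except (ValueError, IndexError):
                logger.warning("skipping malformed %s record in %s", rec.strip(), path)
    return helices, sheets


def _first_listed_ca(residue):
    """The Cα atom of a residue, taking the first-listed altloc if disordered."""
    if "CA" not in residue:
        return None
    atom = residue["CA"]
    if atom.is_disordered():
        children = atom.disordered_get_list()
        atom = min(children, key=lambda a: a.get_serial_number())
    return atom


def read_pdb_ca(
    path: str | Path,
    chain: str | None = None,
    model: int | None = None,
) -> CAStructure:
    """Read one chain of a PDB file as a Cα trace.

    Parameters
    ----------
    path : path to a PDB file.
    chain : chain identifier; default is the first chain of the model.
    model : 0-based model index; default is the first model.

    Exactly one site is produced per residue that has a Cα atom; residues
    without one are skipped with a warning.  For alternate locations the
    first-listed altloc is kept.  Insertion codes are preserved in
    ``residue_ids``.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure(path.stem, str(path))
    models = list(structure)
    if not models:
        raise StructureError(f"{path}: no models found")
    mdl = models[model if model is not None else 0]
    chains = {c.id: c for c in mdl}
    if chain is None:
        chain_obj = next(iter(chains.values()))
    elif chain in chains:
        chain_obj = chains[chain]
    else:
        raise StructureError(
            f"{path}: chain {chain!r} not found; available chains: {sorted(chains)}"
        )

    coords, res_ids = [], []
    for residue in chain_obj:
        hetflag, resseq, icode = residue.get_id()
        if hetflag.strip():  # skip waters / het groups
            continue
        atom = _first_listed_ca(residue)
        if atom is None:
            logger.warning("%s: residue %s%s has no CA atom; skipped", path, resseq, icode.strip())
            continue
        coords.append(np.asarray(atom.get_coord(), dtype=float))
        res_ids.append(f"{resseq}{icode.strip()}")
    if not coords:
        raise EmptyStructureError(f"{path}: no CA atoms in chain {chain_obj.id!r}")

    helices, sheets = _parse_sse_records(path)
    return CAStructure(
        id=f"{path.stem}_{chain_obj.id}".rstrip("_ "),
        coords=np.vstack(coords),
        residue_ids=tuple(res_ids),
        helix_ranges=tuple(helices),
        sheet_ranges=tuple(sheets),
        chain=chain_obj.id,
    )


def write_pdb_ca(s: CAStructure, path: str | Path, chain: str = "A") -> None:
    """Write a Cα-only PDB file (fixed-width ATOM records, 3-decimal coords)."""
    chain_id = (s.chain or chain)[:1] or "A"
    with open(path, "w") as fh:
        for i, ((x, y, z), rid) in enumerate(zip(s.coords, s.residue_ids), start=1):
            icode = " "
            num = rid
            if num and not num[-1].isdigit():
                num, icode = num[:-1], num[-1]
            fh.write(
                f"ATOM  {i:5d}  CA  ALA {chain_id}{int(num):4d}{icode}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}           C  \n"
            )
        fh.write("TER\nEND\n")


# ---------------------------------------------------------------------------
# secondary structure assignment
# ---------------------------------------------------------------------------

def _within(x: float, band: tuple[float, float]) -> bool:
    return band[0] <= x <= band[1]


def _geometric_labels(coords: np.ndarray) -> str:
    n = coords.shape[0]
    labels = np.full(n, "C", dtype="<U1")
    if n < 4:
        return "".join(labels)

    def d(i: int, j: int) -> float:
        return float(np.linalg.norm(coords[i] - coords[j]))

    helix_mark = np.zeros(n, dtype=bool)
    strand_mark = np.zeros(n, dtype=bool)
    for i in range(n - 4):
        if (
            _within(d(i, i + 2), _HELIX_D2)
            and _within(d(i, i + 3), _HELIX_D3)
            and _within(d(i, i + 4), _HELIX_D4)
        ):
            helix_mark[i : i + 5] = True
    for i in range(n - 3):
        if _within(d(i, i + 2), _STRAND_D2) and _within(d(i, i + 3), _STRAND_D3):
            strand_mark[i : i + 4] = True

    labels[strand_mark] = "E"
    labels[helix_mark] = "H"  # helix wins on overlap

    # demote too-short runs to coil
    out = list(labels)
    i = 0
    while i < n:
        j = i
        while j < n and out[j] == out[i]:
            j += 1
        run = j - i
        if (out[i] == "H" and run < _MIN_HELIX_RUN) or (
            out[i] == "E" and run < _MIN_STRAND_RUN
        ):
            for k in range(i, j):
                out[k] = "C"
        i = j
    return "".join(out)


def _record_labels(s: CAStructure) -> str:
    labels = ["C"] * len(s)
    num_by_site: list[int | None] = []
    for rid in s.residue_ids:
        core = rid[:-1] if rid and not rid[-1].isdigit() else rid
        try:
            num_by_site.append(int(core))
        except ValueError:
            num_by_site.append(None)
    for ranges, tag in ((s.helix_ranges, "H"), (s.sheet_ranges, "E")):
        for rec_chain, first, last in ranges:
            if s.chain and rec_chain and rec_chain != s.chain:
                continue
            for i, num in enumerate(num_by_site):
                if num is not None and first <= num <= last:
                    labels[i] = tag
    return "".join(labels)


def assign_sse(
    s: CAStructure,
    mode: str = "geometric",
    labels: str | None = None,
) -> CAStructure:
    """Return a copy of *s* with every site labelled H, E or C.

    mode='geometric' derives labels from Cα window distances only (invariant
    under rigid motion); mode='records' uses HELIX/SHEET ranges kept from
    parsing; mode='provided' takes *labels* verbatim.
    """
    if mode == "geometric":
        new = _geometric_labels(s.coords)
    elif mode == "records":
        new = _record_labels(s)
    elif mode == "provided":
        if labels is None or len(labels) != len(s):
            raise StructureError(
                f"provided labels must have length {len(s)}, "
                f"got {0 if labels is None else len(labels)}"
            )
        if not set(labels) <= SSE_LABELS:
            raise StructureError("provided labels must use only H, E, C")
        new = labels
    else:
        raise ValueError(f"unknown SSE mode {mode!r}")
    logger.debug("SSE assignment (%s) for %s: %s", mode, s.id, new)
    return replace(s, sse=new)
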