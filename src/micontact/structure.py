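"""Surface / contact residue annotation from a reference structure.

Two inputs drive the labels:

* a per-residue relative solvent accessibility table giving, for each
  residue, the percentage accessibility with its domain treated as an
  isolated entity and within the two-domain complex (such tables come
  from JOY- or DSSP-style tools; they are inputs, not computed here);
* atomic coordinates of the reference structure (PDB), from which
  minimum inter-atomic residue-residue distances are taken.

A residue is *surface* when its isolated-domain accessibility exceeds
7% (strict); it is a *contact* when additionally it lies strictly
within 4.5 A of some residue of the partner domain and its
accessibility changes between the isolated and complexed states.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import DomainRangeError, MissingAnnotationError, MicontactError
from .msa import ColumnMask, PairedMSA

#: surface threshold, percent relative accessibility (strict >)
SURFACE_ACCESS_PCT = 7.0
#: inter-domain contact distance cutoff, Angstroms (strict <)
CONTACT_CUTOFF = 4.5
#: minimum |isolated - complex| accessibility change for contact criterion 3
ACCESS_CHANGE_TOL = 0.5

Residue = tuple[int, int]  # (domain, 1-based residue number)


@dataclass(frozen=True)
class ResidueAnnotation:
    domain: int
    resnum: int
    rel_access_isolated: float
    rel_access_complex: float
    surface: bool | None = None
    contact: bool | None = None
    column: int | None = None


@dataclass(frozen=True)
class DistanceMap:
    """Minimum inter-atomic residue-pair distances, Angstroms.

    ``inter`` is keyed (domain-1 residue number, domain-2 residue number);
    ``intra1`` / ``intra2`` by within-domain residue pairs (a < b).
    """

    inter: Mapping[tuple[int, int], float]
    intra1: Mapping[tuple[int, int], float]
    intra2: Mapping[tuple[int, int], float]

    def min_inter_distance(self, domain: int, resnum: int) -> float:
        if domain == 1:
            vals = [d for (r1, _), d in self.inter.items() if r1 == resnum]
        else:
            vals = [d for (_, r2), d in self.inter.items() if r2 == resnum]
        if not vals:
            raise MissingAnnotationError(
                f"no inter-domain distances for domain {domain} residue {resnum}"
            )
        return min(vals)


def min_atom_distances(coords: Mapping[Residue, np.ndarray]) -> DistanceMap:
    """Minimum atom-atom Euclidean distance for every residue pair.

    ``coords`` maps (domain, resnum) to an (n_atoms, 3) array; all atoms
    present are used (hydrogens included if supplied).  A residue is
    never paired with itself in the intra maps.
    """
    for key, xyz in coords.items():
        if np.asarray(xyz).size == 0 or not np.isfinite(xyz).all():
            raise MissingAnnotationError(f"residue {key} has no usable atoms")
    d1 = sorted(r for d, r in coords if d == 1)
    d2 = sorted(r for d, r in coords if d == 2)

    def pair(a: Residue, b: Residue) -> float:
        return float(cdist(np.atleast_2d(coords[a]), np.atleast_2d(coords[b])).min())

    inter = {(r1, r2): pair((1, r1), (2, r2)) for r1 in d1 for r2 in d2}
    intra1 = {(a, b): pair((1, a), (1, b))
              for i, a in enumerate(d1) for b in d1[i + 1:]}
    intra2 = {(a, b): pair((2, a), (2, b))
              for i, a in enumerate(d2) for b in d2[i + 1:]}
    return DistanceMap(inter=inter, intra1=intra1, intra2=intra2)


def load_coords(
    path: str | Path,
    domain1_range: tuple[int, int],
    domain2_range: tuple[int, int],
    chain: str | None = None,
) -> dict[Residue, np.ndarray]:
    """Read PDB coordinates into the (domain, resnum) -> atoms mapping.

    Residues are identified by chain + residue number (+ insertion code
    ignored for numbering into the domain ranges); alternate locations
    are resolved per atom name by highest occupancy, then first.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise MicontactError(f"{path}: structure has no models")
    model = st[0]
    ch = model[chain] if chain is not None else model[0]
    coords: dict[Residue, np.ndarray] = {}
    for res in ch:
        seqid = res.seqid.num
        if domain1_range[0] <= seqid <= domain1_range[1]:
            dom = 1
        elif domain2_range[0] <= seqid <= domain2_range[1]:
            dom = 2
        else:
            continue
        best: dict[str, tuple[float, np.ndarray]] = {}
        for atom in res:
            pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
            prev = best.get(atom.name)
            if prev is None or atom.occ > prev[0]:
                best[atom.name] = (atom.occ, pos)
        if not best:
            raise MissingAnnotationError(f"residue {seqid} has no atoms")
        coords[(dom, seqid)] = np.array([xyz for _, xyz in best.values()])
    return coords


def classify_surface(rel_access_isolated: float,
                     threshold: float = SURFACE_ACCESS_PCT) -> bool:
    """True iff the residue is > ``threshold`` percent accessible (strict)."""
    if not 0.0 <= rel_access_isolated <= 100.0:
        raise MissingAnnotationError(
            f"accessibility {rel_access_isolated} outside [0, 100]"
        )
    return rel_access_isolated > threshold


def label_contacts(
    annotations: Iterable[ResidueAnnotation],
    distances: DistanceMap,
    *,
    surface_threshold: float = SURFACE_ACCESS_PCT,
    contact_cutoff: float = CONTACT_CUTOFF,
    access_change_tol: float = ACCESS_CHANGE_TOL,
) -> list[ResidueAnnotation]:
    """Assign surface and contact labels to every annotated residue.

    Contact requires all three criteria: (1) surface in the isolated
    domain, (2) minimum inter-domain distance strictly below
    ``contact_cutoff``, (3) accessibility differing between the isolated
    and complexed states by more than ``access_change_tol`` points.
    """
    out = []
    for ann in annotations:
        if ann.rel_access_isolated is None or ann.rel_access_complex is None:
            raise MissingAnnotationError(
                f"residue {(ann.domain, ann.resnum)} lacks accessibility data"
            )
        surface = classify_surface(ann.rel_access_isolated, surface_threshold)
        close = distances.min_inter_distance(ann.domain, ann.resnum) < contact_cutoff
        changed = abs(ann.rel_access_isolated - ann.rel_access_complex) > access_change_tol
        out.append(replace(ann, surface=surface,
                           contact=surface and close and changed))
    return out


def annotate_columns(msa: PairedMSA,
                     annotations: Iterable[ResidueAnnotation]
                     ) -> list[ResidueAnnotation]:
    """Attach each residue's alignment column (via the reference row)."""
    out = []
    for ann in annotations:
        try:
            col = msa.residue_column(ann.domain, ann.resnum)
        except DomainRangeError as exc:
            raise DomainRangeError(
                f"residue {(ann.domain, ann.resnum)} not mappable: {exc}"
            ) from None
        out.append(replace(ann, column=col))
    return out


def column_distances(distances: DistanceMap, msa: PairedMSA
                     ) -> dict[tuple[int, int], float]:
    """Within-domain residue distances re-keyed by alignment columns.

    Feeds :func:`micontact.scores.enumerate_patch_triplets`.
    """
    out: dict[tuple[int, int], float] = {}
    for dom, intra in ((1, distances.intra1), (2, distances.intra2)):
        for (a, b), dist in intra.items():
            ca = msa.residue_column(dom, a)
            cb = msa.residue_column(dom, b)
            out[(min(ca, cb), max(ca, cb))] = dist
    return out


# ---------------------------------------------------------------------------
# tabular I/O

_COLUMNS = ["domain", "resnum", "rel_access_isolated", "rel_access_complex",
            "surface", "contact", "column"]


def annotations_to_frame(annotations: Iterable[ResidueAnnotation]) -> pd.DataFrame:
    return pd.DataFrame([{k: getattr(a, k) for k in _COLUMNS}
                         for a in annotations])


def write_annotations(annotations: Iterable[ResidueAnnotation],
                      path: str | Path) -> None:
    annotations_to_frame(annotations).to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> list[ResidueAnnotation]:
    """Read the TSV annotation format (see :func:`write_annotations`).

    Only ``domain``, ``resnum`` and the two accessibility columns are
    required; labels are recomputed by :func:`label_contacts`.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"domain", "resnum", "rel_access_isolated", "rel_access_complex"}
    missing = required - set(df.columns)
    if missing:
        raise MissingAnnotationError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(ResidueAnnotation(
            domain=int(row.domain),
            resnum=int(row.resnum),
            rel_access_isolated=float(row.rel_access_isolated),
            rel_access_complex=float(row.rel_access_complex),
            surface=bool(row.surface) if hasattr(row, "surface") and pd.notna(row.surface) else None,
            contact=bool(row.contact) if hasattr(row, "contact") and pd.notna(row.contact) else None,
            column=int(row.column) if hasattr(row, "column") and pd.notna(row.column) else None,
        ))
    return out
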