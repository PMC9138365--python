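"""Structural metrics for the open/closed conformational transition.

Kabsch least-squares superposition on named atom selections, domain-local
RMSDs between the ligand-free and ligand-bound structures, inter-helix
C-alpha distances that report lid closure, and the precision (RMSD to the
iteratively refined mean) of an NMR conformer ensemble.  Coordinates are
read from PDB or mmCIF files through gemmi.

Named selections follow the secondary-structure assignment of the
194-residue kinase: nine helices (a1: 2-7, a2: 21-32, a3: 39-49, a4: 52-63,
a5: 69-83, a6: 99-109, a7: 122-135, a8: 143-167, a9: 179-193) and a
five-stranded sheet (b1: 9-14, b2: 35-38, b3: 83-89, b4: 114-119,
b5: 170-174).  The b3 range is published with its bounds transposed
("89-83") and is stored here in ascending order.  Two conventions exist for
the mobile fragments - the helix-pair definitions (NMP 39-63, LID 122-167)
and the wider relaxation-analysis windows (39-72, 120-152) - so both are
exposed as named selections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

try:
    import gemmi
except ImportError:  # pragma: no cover
    gemmi = None

__all__ = [
    "StructureEnsemble",
    "Selection",
    "SECONDARY_STRUCTURE",
    "DOMAINS",
    "load_structure",
    "kabsch_superpose",
    "subset_rmsd",
    "ensemble_rmsd_to_mean",
    "interhelix_distance",
]

SECONDARY_STRUCTURE: dict[str, tuple[int, int]] = {
    "a1": (2, 7), "a2": (21, 32), "a3": (39, 49), "a4": (52, 63),
    "a5": (69, 83), "a6": (99, 109), "a7": (122, 135), "a8": (143, 167),
    "a9": (179, 193),
    "b1": (9, 14), "b2": (35, 38), "b3": (83, 89), "b4": (114, 119),
    "b5": (170, 174),
}

#: CORE = the sheet plus the helices that do not move on closure;
#: NMP/LID in the helix-pair convention; *_wide in the relaxation convention
DOMAINS: dict[str, list[tuple[int, int]]] = {
    "CORE": [SECONDARY_STRUCTURE[k] for k in
             ("b1", "b2", "b3", "b4", "b5", "a1", "a2", "a5", "a6", "a9")],
    "NMP": [(39, 63)],
    "LID": [(122, 167)],
    "NMP_wide": [(39, 72)],
    "LID_wide": [(120, 152)],
    "NMP_LID": [(39, 63), (122, 167)],
}

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class Selection:
    """Residue ranges plus an atom-name filter.

    ``atoms`` is "CA", "backbone" (N, CA, C, O) or "heavy" (all
    non-hydrogen atoms).
    """

    ranges: tuple[tuple[int, int], ...]
    atoms: str = "CA"

    @classmethod
    def from_domain(cls, name: str, atoms: str = "CA") -> "Selection":
        return cls(tuple(DOMAINS[name]), atoms)

    def contains(self, residue_number: int) -> bool:
        return any(lo <= residue_number <= hi for lo, hi in self.ranges)

    def wants_atom(self, atom_name: str, element_is_h: bool) -> bool:
        if self.atoms == "CA":
            return atom_name == "CA"
        if self.atoms == "backbone":
            return atom_name in BACKBONE_ATOMS
        if self.atoms == "heavy":
            return not element_is_h
        raise ValueError(f"unknown atom filter {self.atoms!r}")


@dataclass
class StructureEnsemble:
    """Multi-model coordinates: per model, {(residue, atom): xyz}."""

    models: list[dict[tuple[int, str], np.ndarray]]
    name: str = ""

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("ensemble needs at least one model")

    @property
    def n_models(self) -> int:
        return len(self.models)

    def coords(self, selection: Selection, model_index: int = 0) -> np.ndarray:
        keys = self.atom_keys(selection, model_index)
        return np.array([self.models[model_index][k] for k in keys])

    def atom_keys(
        self, selection: Selection, model_index: int = 0
    ) -> list[tuple[int, str]]:
        model = self.models[model_index]
        return sorted(
            k for k in model
            if selection.contains(k[0])
            and selection.wants_atom(
                k[1], k[1].lstrip("0123456789").startswith("H")
            )
        )


def load_structure(path, chain: str | None = None) -> StructureEnsemble:
    """Read a PDB or mmCIF file into an ensemble.

    First chain by default, first altloc, hydrogens retained (filtered at
    selection time).
    """
    if gemmi is None:  # pragma: no cover
        raise ImportError("gemmi is required to read coordinate files")
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    st.remove_alternative_conformations()
    models = []
    for model in st:
        ch = model[0] if chain is None else model[chain]
        atoms: dict[tuple[int, str], np.ndarray] = {}
        for residue in ch:
            num = residue.seqid.num
            for atom in residue:
                atoms[(num, atom.name)] = np.array(
                    [atom.pos.x, atom.pos.y, atom.pos.z]
                )
        models.append(atoms)
    return StructureEnsemble(models, name=st.name)


def _paired_coords(
    mobile: StructureEnsemble,
    reference: StructureEnsemble,
    selection: Selection,
    mobile_model: int = 0,
    reference_model: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    keys_m = set(mobile.atom_keys(selection, mobile_model))
    keys_r = set(reference.atom_keys(selection, reference_model))
    common = sorted(keys_m & keys_r)
    if len(common) < 3:
        only_m = sorted(keys_m - keys_r)[:10]
        only_r = sorted(keys_r - keys_m)[:10]
        raise ValueError(
            f"only {len(common)} paired atoms in selection; unpaired examples: "
            f"mobile-only {only_m}, reference-only {only_r}"
        )
    xm = np.array([mobile.models[mobile_model][k] for k in common])
    xr = np.array([reference.models[reference_model][k] for k in common])
    return xm, xr


def _kabsch(mobile_xyz: np.ndarray, ref_xyz: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal proper rotation R and translation t: R @ x_m + t ~ x_r."""
    cm, cr = mobile_xyz.mean(axis=0), ref_xyz.mean(axis=0)
    h = (mobile_xyz - cm).T @ (ref_xyz - cr)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, cr - rot @ cm


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def kabsch_superpose(
    mobile: StructureEnsemble,
    reference: StructureEnsemble,
    fit_selection: Selection,
    mobile_model: int = 0,
    reference_model: int = 0,
) -> tuple[np.ndarray, np.ndarray, float, StructureEnsemble]:
    """Least-squares rigid-body superposition over ``fit_selection``.

    Returns (rotation, translation, RMSD over the fit selection, transformed
    copy of the mobile structure).  The rotation is proper (det = +1); a
    degenerate (collinear) selection of fewer than 3 atoms is an error.
    """
    xm, xr = _paired_coords(mobile, reference, fit_selection, mobile_model, reference_model)
    rot, trans = _kabsch(xm, xr)
    moved = StructureEnsemble(
        [
            {k: rot @ v + trans for k, v in model.items()}
            for model in mobile.models
        ],
        name=mobile.name,
    )
    return rot, trans, _rmsd(xm @ rot.T + trans, xr), moved


def subset_rmsd(
    mobile: StructureEnsemble,
    reference: StructureEnsemble,
    fit_selection: Selection,
    measure_selection: Selection | None = None,
    mobile_model: int = 0,
    reference_model: int = 0,
) -> float:
    """RMSD over ``measure_selection`` after superposing on ``fit_selection``.

    With ``measure_selection=None`` the fit selection is also measured
    (domain-local alignment).  Fitting on one region and measuring another
    (e.g. fit on the rigid core, measure the mobile lids) quantifies domain
    displacement.
    """
    measure = measure_selection or fit_selection
    _, _, _, moved = kabsch_superpose(
        mobile, reference, fit_selection, mobile_model, reference_model
    )
    xm, xr = _paired_coords(moved, reference, measure, mobile_model, reference_model)
    return _rmsd(xm, xr)


def ensemble_rmsd_to_mean(
    ensemble: StructureEnsemble,
    selection: Selection,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[float, float]:
    """Precision of a conformer ensemble: per-model RMSD to the mean.

    All models are iteratively superposed onto their coordinate average over
    ``selection`` until the average moves by less than ``tol`` Angstrom;
    returns (mean, SD) of the per-model RMSDs to the converged mean.
    """
    if ensemble.n_models < 2:
        raise ValueError("ensemble precision needs at least two models")
    keys = ensemble.atom_keys(selection, 0)
    for m in range(ensemble.n_models):
        if any(k not in ensemble.models[m] for k in keys):
            raise ValueError(f"model {m} is missing atoms of the selection")
    coords = np.array(
        [[ensemble.models[m][k] for k in keys] for m in range(ensemble.n_models)]
    )
    mean = coords[0].copy()
    for _ in range(max_iter):
        aligned = []
        for x in coords:
            rot, trans = _kabsch(x, mean)
            aligned.append(x @ rot.T + trans)
        aligned = np.array(aligned)
        new_mean = aligned.mean(axis=0)
        shift = float(np.max(np.linalg.norm(new_mean - mean, axis=1)))
        coords = aligned
        mean = new_mean
        if shift < tol:
            break
    rmsds = np.array([_rmsd(x, mean) for x in coords])
    return float(rmsds.mean()), float(rmsds.std())


def mean_structure(
    ensemble: StructureEnsemble, selection: Selection | None = None
) -> StructureEnsemble:
    """Single-model ensemble holding the iteratively superposed mean.

    Superposition uses backbone atoms of all residues unless a selection is
    given; the mean is taken over all atoms shared by every model.
    """
    sel = selection or Selection(((1, 10**6),), "backbone")
    keys_fit = ensemble.atom_keys(sel, 0)
    all_keys = sorted(
        set.intersection(*(set(m.keys()) for m in ensemble.models))
    )
    coords = np.array(
        [[m[k] for k in all_keys] for m in ensemble.models]
    )
    fit_idx = [all_keys.index(k) for k in keys_fit]
    mean_fit = coords[0][fit_idx]
    for _ in range(100):
        aligned = []
        for x in coords:
            rot, trans = _kabsch(x[fit_idx], mean_fit)
            aligned.append(x @ rot.T + trans)
        coords = np.array(aligned)
        new_mean = coords[:, fit_idx].mean(axis=0)
        if np.max(np.linalg.norm(new_mean - mean_fit, axis=1)) < 1e-6:
            mean_fit = new_mean
            break
        mean_fit = new_mean
    mean_all = coords.mean(axis=0)
    return StructureEnsemble(
        [dict(zip(all_keys, mean_all))], name=ensemble.name + "_mean"
    )


def interhelix_distance(
    structure: StructureEnsemble, residue_a: int, residue_b: int
) -> tuple[float, float, float]:
    """C-alpha distance between two residues.

    Returns (distance in model 0, ensemble mean, ensemble SD); for a
    single-model structure the three numbers coincide.
    """
    dists = []
    for m, model in enumerate(structure.models):
        try:
            pa, pb = model[(residue_a, "CA")], model[(residue_b, "CA")]
        except KeyError as exc:
            raise ValueError(
                f"model {m}: missing C-alpha for residue {exc.args[0][0]}"
            ) from None
        dists.append(float(np.linalg.norm(pa - pb)))
    arr = np.array(dists)
    return dists[0], float(arr.mean()), float(arr.std())
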