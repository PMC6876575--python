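"""Structural metrics: superposition, actin twist, contacts, buried area, clashes.

Operates on single structures or multi-model ensembles (PDB / mmCIF read via
gemmi).  The metrics implemented here are the standard desk analyses of an
actin-binding-protein structure study:

* least-squares (Kabsch) superposition on a residue/atom selection,
* the actin "twist" angle: superpose two actins on their inner domain
  (subdomains 3+4) and measure the rigid rotation that carries the reference
  outer domain (subdomain 1) onto the target's,
* inter-chain residue contacts (a residue of either chain counts when any of
  its heavy atoms lies within a cutoff, default 3 Å, of the other chain) and
  per-residue contact frequencies over an ensemble after discarding an
  equilibration prefix,
* buried interface area via Shrake-Rupley solvent-accessible surface area,
  buried = (SASA_A + SASA_B - SASA_AB) / 2,
* steric clashes (heavy-atom pairs closer than the sum of van der Waals
  radii minus a 0.4 Å tolerance) and named inter-atom distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

# Bondi van der Waals radii (Å); fallback for unlisted elements is 1.80 Å.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
    "MG": 1.73, "CA": 2.31, "ZN": 1.39, "FE": 1.80, "K": 2.75, "NA": 2.27,
}
DEFAULT_VDW = 1.80

# Canonical actin subdomain residue ranges (configurable per call).
ACTIN_SUBDOMAINS = {
    "SD1": [(1, 32), (70, 144), (338, 375)],
    "SD2": [(33, 69)],
    "SD3": [(145, 180), (270, 337)],
    "SD4": [(181, 269)],
}

_WATER_NAMES = {"HOH", "WAT", "DOD"}


@dataclass
class AtomFrame:
    """One coordinate frame: parallel per-atom arrays plus (N, 3) Å coordinates."""

    chain: np.ndarray
    resnum: np.ndarray
    resname: np.ndarray
    atom: np.ndarray
    element: np.ndarray
    xyz: np.ndarray
    altloc: np.ndarray
    occupancy: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.resnum)

    def mask(
        self,
        chain: str | None = None,
        resnums: np.ndarray | None = None,
        atoms: set[str] | None = None,
        heavy: bool = False,
    ) -> np.ndarray:
        m = np.ones(len(self), dtype=bool)
        if chain is not None:
            m &= self.chain == chain
        if resnums is not None:
            m &= np.isin(self.resnum, resnums)
        if atoms is not None:
            m &= np.isin(self.atom, list(atoms))
        if heavy:
            m &= self.element != "H"
        return m

    def select(self, **kwargs) -> "AtomFrame":
        m = self.mask(**kwargs)
        return AtomFrame(
            chain=self.chain[m],
            resnum=self.resnum[m],
            resname=self.resname[m],
            atom=self.atom[m],
            element=self.element[m],
            xyz=self.xyz[m],
            altloc=self.altloc[m],
            occupancy=self.occupancy[m],
        )

    def chains(self) -> list[str]:
        return sorted(set(self.chain.tolist()))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "AtomFrame":
        out = self.select()
        out.xyz = self.xyz @ rotation.T + translation
        return out


@dataclass
class StructureModel:
    """A structure as a list of coordinate frames (one per model for ensembles)."""

    frames: list[AtomFrame]

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> AtomFrame:
        return self.frames[i]


def _dedup_altlocs(frame: AtomFrame) -> AtomFrame:
    """Keep the highest-occupancy conformer per (chain, resnum, atom)."""
    if np.all(frame.altloc == ""):
        return frame
    order = np.lexsort((-frame.occupancy, frame.atom, frame.resnum, frame.chain))
    keys = list(zip(frame.chain[order], frame.resnum[order], frame.atom[order]))
    seen: set = set()
    keep_sorted = np.zeros(len(frame), dtype=bool)
    for i, k in enumerate(keys):
        if k not in seen:
            seen.add(k)
            keep_sorted[i] = True
    keep = np.zeros(len(frame), dtype=bool)
    keep[order[keep_sorted]] = True
    m = frame
    return AtomFrame(
        chain=m.chain[keep], resnum=m.resnum[keep], resname=m.resname[keep],
        atom=m.atom[keep], element=m.element[keep], xyz=m.xyz[keep],
        altloc=m.altloc[keep], occupancy=m.occupancy[keep],
    )


def read_structure(path: str | Path, *, exclude_waters: bool = True) -> StructureModel:
    """Read a (possibly multi-model) PDB or mmCIF file into a StructureModel."""
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    frames: list[AtomFrame] = []
    for model in st:
        rows = {k: [] for k in
                ("chain", "resnum", "resname", "atom", "element", "altloc", "occupancy")}
        coords = []
        for chain in model:
            for res in chain:
                if exclude_waters and res.name in _WATER_NAMES:
                    continue
                for at in res:
                    rows["chain"].append(chain.name)
                    rows["resnum"].append(res.seqid.num)
                    rows["resname"].append(res.name)
                    rows["atom"].append(at.name)
                    rows["element"].append(at.element.name.upper())
                    rows["altloc"].append(at.altloc if at.altloc else "")
                    rows["occupancy"].append(at.occ)
                    coords.append([at.pos.x, at.pos.y, at.pos.z])
        frame = AtomFrame(
            chain=np.array(rows["chain"]),
            resnum=np.array(rows["resnum"], dtype=int),
            resname=np.array(rows["resname"]),
            atom=np.array(rows["atom"]),
            element=np.array(rows["element"]),
            xyz=np.array(coords, dtype=float),
            altloc=np.array(rows["altloc"]),
            occupancy=np.array(rows["occupancy"], dtype=float),
        )
        frames.append(_dedup_altlocs(frame))
    if not frames:
        raise ValueError(f"no models found in {path}")
    return StructureModel(frames=frames)


# ---------------------------------------------------------------------------
# Superposition


@dataclass
class Superposition:
    """Optimal rigid transform mapping mobile onto reference, with RMSD (Å)."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int

    @property
    def angle_deg(self) -> float:
        return rotation_angle_deg(self.rotation)

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return xyz @ self.rotation.T + self.translation


def kabsch(mobile_xyz: np.ndarray, ref_xyz: np.ndarray) -> Superposition:
    """Least-squares rigid superposition (Kabsch, via SVD) of paired points."""
    p = np.asarray(mobile_xyz, dtype=float)
    q = np.asarray(ref_xyz, dtype=float)
    if p.shape != q.shape or p.ndim != 2 or p.shape[1] != 3:
        raise ValueError("paired (N, 3) coordinate arrays required")
    if len(p) < 3:
        raise ValueError("need at least 3 paired atoms")
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    h = (p - pc).T @ (q - qc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = qc - rot @ pc
    moved = p @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - q) ** 2, axis=1))))
    return Superposition(rotation=rot, translation=trans, rmsd=rmsd, n_atoms=len(p))


def rotation_angle_deg(rotation: np.ndarray) -> float:
    """Rotation angle (degrees) of a 3x3 rotation matrix."""
    cos = np.clip((np.trace(rotation) - 1.0) / 2.0, -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def _paired_coords(
    mobile: AtomFrame,
    reference: AtomFrame,
    *,
    chain: str | None = None,
    ref_chain: str | None = None,
    resnums: np.ndarray | None = None,
    atoms: set[str] | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Match atoms 1:1 by (residue number, atom name) within the selections."""
    if atoms is None:
        atoms = {"CA"}
    a = mobile.select(chain=chain, resnums=resnums, atoms=atoms, heavy=True)
    b = reference.select(chain=ref_chain, resnums=resnums, atoms=atoms, heavy=True)

    def keyed(fr: AtomFrame) -> dict:
        keys = {}
        for i in range(len(fr)):
            k = (int(fr.resnum[i]), str(fr.atom[i]))
            if k in keys:
                raise ValueError(f"ambiguous atom mapping for {k}")
            keys[k] = i
        return keys

    ka, kb = keyed(a), keyed(b)
    common = sorted(set(ka) & set(kb))
    ia = [ka[k] for k in common]
    ib = [kb[k] for k in common]
    n_ref = len(kb)
    return a.xyz[ia], b.xyz[ib], n_ref


def superpose(
    mobile: AtomFrame,
    reference: AtomFrame,
    *,
    chain: str | None = None,
    ref_chain: str | None = None,
    resnums: np.ndarray | None = None,
    atoms: set[str] | None = None,
) -> Superposition:
    """Superpose ``mobile`` onto ``reference`` on matched atoms (Cα by default)."""
    p, q, _ = _paired_coords(
        mobile, reference, chain=chain, ref_chain=ref_chain, resnums=resnums, atoms=atoms
    )
    return kabsch(p, q)


# ---------------------------------------------------------------------------
# Actin twist angle


@dataclass
class TwistResult:
    """Outer-domain rotation angle after inner-domain superposition."""

    angle_deg: float
    inner_rmsd: float
    outer_rmsd: float
    n_inner: int
    n_outer: int


def _subdomain_resnums(ranges: list[tuple[int, int]]) -> np.ndarray:
    return np.concatenate([np.arange(lo, hi + 1) for lo, hi in ranges])


def actin_twist_angle(
    structure: AtomFrame,
    chain: str,
    reference: AtomFrame,
    ref_chain: str,
    *,
    subdomains: dict | None = None,
    coverage_floor: float = 0.8,
) -> TwistResult:
    """Twist of an actin conformation relative to a reference actin.

    Both actins are first superposed on the Cα atoms of the inner domain
    (subdomains 3 and 4); the reported angle is the rotation of the best-fit
    rigid transform mapping the reference outer domain (subdomain 1) Cα set
    onto the target's.  The reference measured against itself gives 0°.
    """
    sd = subdomains or ACTIN_SUBDOMAINS
    inner = _subdomain_resnums(sd["SD3"] + sd["SD4"])
    outer = _subdomain_resnums(sd["SD1"])

    p_in, q_in, n_ref_in = _paired_coords(
        structure, reference, chain=chain, ref_chain=ref_chain, resnums=inner
    )
    p_out, q_out, n_ref_out = _paired_coords(
        structure, reference, chain=chain, ref_chain=ref_chain, resnums=outer
    )
    for got, n_ref, label in ((len(p_in), n_ref_in, "inner"), (len(p_out), n_ref_out, "outer")):
        if n_ref == 0 or got < coverage_floor * n_ref or got < 3:
            raise ValueError(
                f"{label}-domain Cα coverage {got}/{n_ref} below floor {coverage_floor}"
            )

    inner_sup = kabsch(p_in, q_in)  # target -> reference frame
    p_out_aligned = inner_sup.apply(p_out)
    outer_sup = kabsch(q_out, p_out_aligned)  # reference outer -> target outer
    return TwistResult(
        angle_deg=outer_sup.angle_deg,
        inner_rmsd=inner_sup.rmsd,
        outer_rmsd=outer_sup.rmsd,
        n_inner=len(p_in),
        n_outer=len(p_out),
    )


# ---------------------------------------------------------------------------
# Inter-chain contacts


@dataclass
class ContactResult:
    """Per-frame inter-chain contact counts and per-residue contact frequencies.

    A residue is "in contact" when any of its heavy atoms lies within
    ``cutoff`` of any heavy atom of the other chain; the per-frame count sums
    contacting residues over both chains.  Frequencies are fractions of the
    post-equilibration frames in which each residue is in contact.
    """

    per_frame_counts: np.ndarray
    frequencies: pd.DataFrame  # columns: chain, resnum, resname, frequency
    cutoff: float
    skip_frames: int

    def summary(self) -> dict:
        q25, med, q75 = np.percentile(self.per_frame_counts, [25, 50, 75])
        return {
            "median": float(med), "q25": float(q25), "q75": float(q75),
            "mean": float(np.mean(self.per_frame_counts)),
            "n_frames": int(len(self.per_frame_counts)),
        }


def _frame_contacts(
    frame: AtomFrame, chain_a: str, chain_b: str, cutoff: float
) -> tuple[set, set]:
    a = frame.select(chain=chain_a, heavy=True)
    b = frame.select(chain=chain_b, heavy=True)
    if len(a) == 0 or len(b) == 0:
        raise ValueError(f"chain {chain_a if len(a) == 0 else chain_b} not present")
    pairs = cKDTree(a.xyz).query_ball_tree(cKDTree(b.xyz), r=cutoff)
    res_a: set = set()
    res_b: set = set()
    for i, js in enumerate(pairs):
        if js:
            res_a.add((chain_a, int(a.resnum[i]), str(a.resname[i])))
            for j in js:
                res_b.add((chain_b, int(b.resnum[j]), str(b.resname[j])))
    return res_a, res_b


def interchain_contacts(
    model: StructureModel | AtomFrame,
    chain_a: str,
    chain_b: str,
    cutoff: float = 3.0,
    skip_frames: int = 0,
) -> ContactResult:
    """Count inter-chain residue contacts per frame and per-residue frequencies.

    ``skip_frames`` discards an equilibration prefix of the ensemble (e.g.
    the first 500 ns of a trajectory expressed in frames) before computing
    counts and frequencies.
    """
    frames = model.frames if isinstance(model, StructureModel) else [model]
    frames = frames[skip_frames:]
    if not frames:
        raise ValueError("no frames left after equilibration skip")
    counts = np.zeros(len(frames), dtype=int)
    freq: dict = {}
    for k, frame in enumerate(frames):
        res_a, res_b = _frame_contacts(frame, chain_a, chain_b, cutoff)
        counts[k] = len(res_a) + len(res_b)
        for key in res_a | res_b:
            freq[key] = freq.get(key, 0) + 1
    rows = [
        {"chain": c, "resnum": r, "resname": n, "frequency": v / len(frames)}
        for (c, r, n), v in sorted(freq.items())
    ]
    freq_df = pd.DataFrame(rows, columns=["chain", "resnum", "resname", "frequency"])
    return ContactResult(
        per_frame_counts=counts, frequencies=freq_df, cutoff=cutoff, skip_frames=skip_frames
    )


def ns_to_frames(skip_ns: float, ns_per_frame: float) -> int:
    """Convert an equilibration time (ns) to a frame count for ``skip_frames``."""
    if ns_per_frame <= 0:
        raise ValueError("ns_per_frame must be > 0")
    return int(np.ceil(skip_ns / ns_per_frame))


# ---------------------------------------------------------------------------
# Solvent-accessible surface area / buried interface


@dataclass
class InterfaceArea:
    """Buried interface area between two chains, from Shrake-Rupley SASA."""

    buried: float  # Å^2
    sasa_a: float
    sasa_b: float
    sasa_complex: float
    probe_radius: float
    n_points: int


def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_VDW)


def shrake_rupley_sasa(
    xyz: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å^2) by test-point sampling.

    Each atom's solvent sphere (vdW + probe radius) is sampled with a
    golden-spiral lattice of ``n_points``; a point is accessible when it lies
    outside every neighbor's solvent sphere.
    """
    xyz = np.asarray(xyz, dtype=float)
    radii = np.asarray(radii, dtype=float) + probe_radius
    n = len(xyz)
    if n == 0:
        raise ValueError("no atoms")
    unit = _sphere_points(n_points)
    tree = cKDTree(xyz)
    max_r = radii.max()
    out = np.zeros(n)
    for i in range(n):
        pts = xyz[i] + radii[i] * unit
        nb = [j for j in tree.query_ball_point(xyz[i], radii[i] + max_r) if j != i]
        if nb:
            d2 = np.sum((pts[:, None, :] - xyz[nb][None, :, :]) ** 2, axis=2)
            buried_pts = np.any(d2 < (radii[nb] ** 2)[None, :], axis=1)
            acc = np.count_nonzero(~buried_pts)
        else:
            acc = n_points
        out[i] = 4.0 * np.pi * radii[i] ** 2 * acc / n_points
    return out


def _chain_sasa(frame: AtomFrame, probe: float, n_points: int) -> float:
    if len(frame) == 0:
        raise ValueError("zero-atom chain")
    radii = np.array([vdw_radius(e) for e in frame.element])
    return float(shrake_rupley_sasa(frame.xyz, radii, probe, n_points).sum())


def buried_interface_area(
    frame: AtomFrame,
    chain_a: str,
    chain_b: str,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> InterfaceArea:
    """Buried area between two chains: (SASA_A + SASA_B - SASA_AB) / 2.

    Hydrogens are excluded; radii are the Bondi set.  The estimate converges
    as ``n_points`` grows (default 960 is well within 1% of convergence for
    protein-sized chains).
    """
    a = frame.select(chain=chain_a, heavy=True)
    b = frame.select(chain=chain_b, heavy=True)
    sasa_a = _chain_sasa(a, probe_radius, n_points)
    sasa_b = _chain_sasa(b, probe_radius, n_points)
    ab = AtomFrame(
        chain=np.concatenate([a.chain, b.chain]),
        resnum=np.concatenate([a.resnum, b.resnum]),
        resname=np.concatenate([a.resname, b.resname]),
        atom=np.concatenate([a.atom, b.atom]),
        element=np.concatenate([a.element, b.element]),
        xyz=np.vstack([a.xyz, b.xyz]),
        altloc=np.concatenate([a.altloc, b.altloc]),
        occupancy=np.concatenate([a.occupancy, b.occupancy]),
    )
    sasa_ab = _chain_sasa(ab, probe_radius, n_points)
    return InterfaceArea(
        buried=0.5 * (sasa_a + sasa_b - sasa_ab),
        sasa_a=sasa_a,
        sasa_b=sasa_b,
        sasa_complex=sasa_ab,
        probe_radius=probe_radius,
        n_points=n_points,
    )


# ---------------------------------------------------------------------------
# Clashes and named distances


def clash_and_distance_report(
    frame: AtomFrame,
    chain_a: str,
    chain_b: str,
    *,
    tolerance: float = 0.4,
    named_pairs: list[tuple[tuple[str, int, str], tuple[str, int, str]]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Steric clashes between two chains plus requested named atom distances.

    A clash is a heavy-atom pair with distance below the sum of the two
    Bondi vdW radii minus ``tolerance`` (0.4 Å, the common steric-clash
    convention).  ``named_pairs`` entries are ((chain, resnum, atom_name),
    (chain, resnum, atom_name)); their distances are returned in Å.
    """
    a = frame.select(chain=chain_a, heavy=True)
    b = frame.select(chain=chain_b, heavy=True)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both chains must be present")
    ra = np.array([vdw_radius(e) for e in a.element])
    rb = np.array([vdw_radius(e) for e in b.element])
    max_thresh = ra.max() + rb.max() - tolerance
    pairs = cKDTree(a.xyz).query_ball_tree(cKDTree(b.xyz), r=max_thresh)
    rows = []
    for i, js in enumerate(pairs):
        for j in js:
            d = float(np.linalg.norm(a.xyz[i] - b.xyz[j]))
            if d < ra[i] + rb[j] - tolerance:
                rows.append(
                    {
                        "chainA": chain_a, "resnumA": int(a.resnum[i]),
                        "resnameA": str(a.resname[i]), "atomA": str(a.atom[i]),
                        "chainB": chain_b, "resnumB": int(b.resnum[j]),
                        "resnameB": str(b.resname[j]), "atomB": str(b.atom[j]),
                        "distance": d,
                        "overlap": ra[i] + rb[j] - tolerance - d,
                    }
                )
    clashes = pd.DataFrame(
        rows,
        columns=["chainA", "resnumA", "resnameA", "atomA", "chainB", "resnumB",
                 "resnameB", "atomB", "distance", "overlap"],
    )

    dist_rows = []
    for (c1, r1, at1), (c2, r2, at2) in named_pairs or []:
        s1 = frame.select(chain=c1, resnums=np.array([r1]), atoms={at1})
        s2 = frame.select(chain=c2, resnums=np.array([r2]), atoms={at2})
        if len(s1) != 1 or len(s2) != 1:
            raise ValueError(f"named atom not found or ambiguous: {(c1, r1, at1)} / {(c2, r2, at2)}")
        dist_rows.append(
            {
                "label": f"{c1}:{r1}:{at1}-{c2}:{r2}:{at2}",
                "distance": float(np.linalg.norm(s1.xyz[0] - s2.xyz[0])),
            }
        )
    distances = pd.DataFrame(dist_rows, columns=["label", "distance"])
    return clashes, distances
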