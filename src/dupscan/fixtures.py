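"""Deterministic synthetic backbones and corpora with known ground truth.

Real depositions cannot ship with a test suite, so every stage of the
pipeline is exercised on parametric fixtures instead: ideal-geometry
helical backbones whose bond lengths and angles are exact by construction,
plus controlled duplicates (exact copies, rigid-motion copies, sub-Å
perturbations, residue-label swaps) and decoys (mirror images, chains of a
different twist).  Because the geometry is parametric, the planted maximum
deviation of every duplicate pair is known exactly, which turns recall and
false-positive checks into sharp assertions rather than statistics.

Perturbation vectors are drawn uniformly in the ball of radius δ, so
``max_dev <= δ`` is a hard bound, not a probabilistic one.

A fixed seed reproduces a corpus byte for byte.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import gemmi
import numpy as np

from .errors import BadMode, DegenerateGeometry
from .geometry import RigidMotion
from .invariant import BackboneChain
from .structure_io import STANDARD_AA

_ONE_TO_THREE = {v: k for k, v in STANDARD_AA.items()}
_AA_LETTERS = sorted(STANDARD_AA.values())

DUPLICATE_MODES = ("exact", "perturb", "label_swap", "mirror", "rigid_copy")


@dataclass(frozen=True)
class HelixGeometry:
    """Parameters of the ideal helical backbone.

    Bond lengths and the N–Cα–C angle match standard peptide values;
    twist/rise/radius approximate an α-helix.  Within each residue the
    stated bond lengths and angle hold exactly; the inter-residue peptide
    bond is whatever the screw construction yields.
    """

    bond_n_ca: float = 1.458       # Å
    bond_ca_c: float = 1.525       # Å
    angle_n_ca_c: float = 111.2    # degrees
    twist: float = 99.1            # degrees per residue about the helix axis
    rise: float = 1.5              # Å per residue along the axis
    radius: float = 2.3            # Å, Cα distance from the axis


def _template_residue(geom: HelixGeometry) -> np.ndarray:
    """N, Cα, C of the template residue (z = 0 plane), shape (3, 3)."""
    if min(geom.bond_n_ca, geom.bond_ca_c) <= 0 or geom.radius < 0:
        raise DegenerateGeometry("bond lengths and radius must be positive")
    ang = math.radians(geom.angle_n_ca_c)
    if not 0.0 < ang < math.pi:
        raise DegenerateGeometry("N-CA-C angle must lie strictly between 0 and 180 deg")
    ca = np.array([geom.radius, 0.0, 0.0])
    # N along a fixed in-plane direction; C at the stated angle from it
    theta_n = math.radians(60.0)
    theta_c = theta_n + ang
    n = ca + geom.bond_n_ca * np.array([math.cos(theta_n), math.sin(theta_n), 0.0])
    c = ca + geom.bond_ca_c * np.array([math.cos(theta_c), math.sin(theta_c), 0.0])
    return np.stack([n, ca, c])


def generate_backbone(
    m: int,
    geometry: HelixGeometry | None = None,
    seed: int = 0,
    entry_id: str = "SYN",
    chain_id: str = "A",
) -> BackboneChain:
    """Generate an ideal helical backbone of ``m`` residues.

    Residue ``i`` is the template residue under the i-th power of the screw
    motion (rotation by ``twist`` about z, translation ``rise`` along z),
    so the relation between consecutive residues is a fixed rigid motion
    and all invariant rows beyond the first are identical.  The seed fixes
    the residue labels and a random overall pose; it does not change the
    internal geometry.
    """
    geom = geometry or HelixGeometry()
    if m < 2:
        raise DegenerateGeometry("need at least 2 residues")
    rng = np.random.default_rng(seed)
    template = _template_residue(geom)
    tw = math.radians(geom.twist)
    coords = np.empty((m, 3, 3))
    for i in range(m):
        ct, st = math.cos(tw * i), math.sin(tw * i)
        R = np.array([[ct, -st, 0.0], [st, ct, 0.0], [0.0, 0.0, 1.0]])
        coords[i] = template @ R.T
        coords[i, :, 2] += geom.rise * i
    pose = RigidMotion.random(rng, translation_scale=20.0)
    coords = pose.apply(coords.reshape(-1, 3)).reshape(m, 3, 3)
    codes = [str(rng.choice(_AA_LETTERS)) for _ in range(m)]
    return BackboneChain(
        entry_id=entry_id,
        chain_id=chain_id,
        residue_numbers=np.arange(1, m + 1),
        aa_codes=codes,
        n=coords[:, 0], ca=coords[:, 1], c=coords[:, 2],
    )


def make_duplicate(
    chain: BackboneChain,
    mode: str,
    delta: float = 0.0,
    k: int = 0,
    seed: int = 0,
    entry_id: str | None = None,
    chain_id: str | None = None,
) -> BackboneChain:
    """Derive a duplicate or decoy from an existing chain.

    Modes: ``exact`` (coordinates copied), ``perturb`` (each atom displaced
    by an independent vector of norm <= ``delta``), ``label_swap`` (``k``
    residue codes changed, coordinates untouched — the adversarial
    relabeling scenario), ``mirror`` (point reflection through the
    centroid), ``rigid_copy`` (random rotation + translation).
    """
    if mode not in DUPLICATE_MODES:
        raise BadMode(f"unknown mode {mode!r}; expected one of {DUPLICATE_MODES}")
    rng = np.random.default_rng(seed)
    atoms = chain.atoms().copy()
    codes = list(chain.aa_codes)
    if mode == "perturb":
        direction = rng.normal(size=atoms.shape)
        direction /= np.linalg.norm(direction, axis=1)[:, None]
        radius = delta * rng.uniform(0.0, 1.0, size=len(atoms)) ** (1.0 / 3.0)
        atoms = atoms + direction * radius[:, None]
    elif mode == "label_swap":
        idx = rng.choice(chain.m, size=k, replace=False)
        for i in idx:
            choices = [a for a in _AA_LETTERS if a != codes[i]]
            codes[i] = str(rng.choice(choices))
    elif mode == "mirror":
        centroid = atoms.mean(axis=0)
        atoms = 2 * centroid - atoms
    elif mode == "rigid_copy":
        atoms = RigidMotion.random(rng).apply(atoms)
    dup = chain.with_coords(
        atoms,
        entry_id=entry_id if entry_id is not None else chain.entry_id + "d",
        chain_id=chain_id,
    )
    dup.aa_codes = codes
    return dup


# ---------------------------------------------------------------------------
# corpus emission

@dataclass
class FixtureSpec:
    """Recipe for a synthetic corpus with planted ground truth.

    Planted near-duplicates follow the regimes observed among confirmed
    duplicate depositions: exact coordinate copies, relabeled copies,
    rigid-motion copies, and uniform sub-grid coordinate shifts of
    ``delta`` Å (the mÅ-scale axis offsets real redeposition pairs show).
    Decoys that must never be reported: mirror images and far-perturbed
    copies (per-atom jitter of ``far_delta``, an order of magnitude above
    the duplicate threshold).
    """

    n_chains: int = 10
    length_range: tuple[int, int] = (20, 60)
    geometry: HelixGeometry = field(default_factory=HelixGeometry)
    delta: float = 0.001            # Å, uniform shift of planted near-duplicates
    far_delta: float = 0.1         # Å, per-atom jitter of far decoys
    n_exact: int = 1
    n_perturbed: int = 1
    n_label_swap: int = 1
    n_rigid_copy: int = 1
    n_mirror: int = 1               # decoys: must NOT be reported
    n_far_perturbed: int = 1        # decoys: must NOT be reported
    label_swap_k: int = 9
    include_filter_violations: bool = False
    include_group_deposition: bool = False
    include_same_entry_pair: bool = False
    seed: int = 0


@dataclass
class PlantedPair:
    entry_id1: str
    chain_id1: str
    entry_id2: str
    chain_id2: str
    category: str                   # exact | perturbed | label_swap | rigid_copy
    planted_max_dev: float


@dataclass
class GroundTruth:
    """Planted duplicate pairs (and decoy inventory) of an emitted corpus."""

    pairs: list[PlantedPair] = field(default_factory=list)
    decoys: list[str] = field(default_factory=list)   # entry ids that must not be reported

    def to_json(self, path: str | Path) -> None:
        payload = {"pairs": [asdict(p) for p in self.pairs], "decoys": self.decoys}
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @staticmethod
    def from_json(path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return GroundTruth(
            pairs=[PlantedPair(**p) for p in payload["pairs"]],
            decoys=payload["decoys"],
        )


def _cube_rotations() -> list[np.ndarray]:
    """The 24 proper rotations of the cube (signed permutation matrices)."""
    import itertools

    out = []
    for perm in itertools.permutations(range(3)):
        for signs in itertools.product((1.0, -1.0), repeat=3):
            R = np.zeros((3, 3))
            for row, col in enumerate(perm):
                R[row, col] = signs[row]
            if np.linalg.det(R) > 0:
                out.append(R)
    return out


_CUBE_ROTATIONS = _cube_rotations()


def grid_rigid_motion(rng: np.random.Generator) -> RigidMotion:
    """A rigid motion that maps the 0.001 Å coordinate grid onto itself:
    a cube rotation plus a translation in whole milli-Å.  Coordinates of a
    planted rigid copy then survive file serialization exactly."""
    R = _CUBE_ROTATIONS[int(rng.integers(len(_CUBE_ROTATIONS)))]
    t = rng.integers(-20000, 20001, size=3) * 0.001
    return RigidMotion(R, t)


def to_gemmi_structure(
    chains: list[BackboneChain],
    entry_id: str,
    resolution: float = 2.0,
    r_free: float | None = 0.25,
    group_deposition: bool = False,
    raw_residues: list | None = None,
) -> gemmi.Structure:
    """Assemble a gemmi Structure (with fabricated headers) from backbones."""
    st = gemmi.Structure()
    st.name = entry_id.upper()
    st.resolution = resolution
    st.info["_entry.id"] = entry_id.upper()
    st.info["_struct.title"] = f"SYNTHETIC BACKBONE FIXTURE {entry_id.upper()}"
    st.info["_exptl.method"] = "X-RAY DIFFRACTION"
    if group_deposition:
        st.info["_struct_keywords.text"] = "GROUP DEPOSITION, SYNTHETIC FIXTURE"
    else:
        st.info["_struct_keywords.text"] = "SYNTHETIC FIXTURE"
    remarks = [f"REMARK   2 RESOLUTION.    {resolution:.2f} ANGSTROMS."]
    if r_free is not None:
        remarks.append(f"REMARK   3   FREE R VALUE                     : {r_free:.4f}")
    st.raw_remarks = remarks
    model = gemmi.Model("1")
    for bb in chains:
        ch = gemmi.Chain(bb.chain_id)
        for i in range(bb.m):
            res = gemmi.Residue()
            res.name = _ONE_TO_THREE.get(bb.aa_codes[i], "UNK")
            res.seqid = gemmi.SeqId(int(bb.residue_numbers[i]), " ")
            for name, el, pos in (
                ("N", "N", bb.n[i]), ("CA", "C", bb.ca[i]), ("C", "C", bb.c[i]),
            ):
                a = gemmi.Atom()
                a.name = name
                a.element = gemmi.Element(el)
                a.pos = gemmi.Position(*pos)
                a.occ = 1.0
                a.b_iso = 20.0
                res.add_atom(a)
            ch.add_residue(res)
        model.add_chain(ch)
    for raw in raw_residues or []:
        # pre-built gemmi chains for filter-violation fixtures
        model.add_chain(raw)
    st.add_model(model)
    st.setup_entities()
    return st


def write_entry(st: gemmi.Structure, pdb_path: Path | None, cif_path: Path | None,
                r_free: float | None = None) -> None:
    """Write a structure as PDB and/or mmCIF with matching metadata."""
    if pdb_path is not None:
        pdb_path.write_text(st.make_pdb_string())
    if cif_path is not None:
        doc = st.make_mmcif_document()
        block = doc.sole_block()
        block.set_pair("_refine.ls_d_res_high", f"{st.resolution:.2f}")
        if r_free is not None:
            block.set_pair("_refine.ls_R_factor_R_free", f"{r_free:.4f}")
        cif_path.write_text(doc.as_string())


def _violation_chains(geom: HelixGeometry, seed: int):
    """One gemmi-free description per cleaning category; built as backbones then damaged."""
    out = []
    base = generate_backbone(12, geom, seed=seed, entry_id="VIO", chain_id="A")
    out.append(("partial_occupancy", base, {"occ_atom": (3, "CA", 0.5)}))
    base2 = generate_backbone(12, geom, seed=seed + 1, entry_id="VIO", chain_id="A")
    out.append(("nonconsecutive_numbering", base2, {"renumber_from": 5}))
    base3 = generate_backbone(12, geom, seed=seed + 2, entry_id="VIO", chain_id="A")
    out.append(("missing_mainchain", base3, {"drop_atom": (6, "N")}))
    base4 = generate_backbone(12, geom, seed=seed + 3, entry_id="VIO", chain_id="A")
    out.append(("nonstandard_residue", base4, {"rename_residue": (4, "MSE")}))
    return out


def _write_violation_entries(out_pdb: Path, out_cif: Path, geom: HelixGeometry,
                             seed: int, next_idx: int) -> int:
    idx = next_idx

    def emit(st: gemmi.Structure, r_free: float):
        nonlocal idx
        eid = f"v{idx:03d}"
        st.name = eid.upper()
        st.info["_entry.id"] = eid.upper()
        write_entry(st, out_pdb / f"{eid}.pdb", out_cif / f"{eid}.cif", r_free=r_free)
        idx += 1

    for category, bb, damage in _violation_chains(geom, seed):
        st = to_gemmi_structure([bb], "TMP", resolution=2.0, r_free=0.25)
        chain = st[0]["A"]
        if "occ_atom" in damage:
            ridx, aname, occ = damage["occ_atom"]
            chain[ridx][aname][0].occ = occ
        if "renumber_from" in damage:
            start = damage["renumber_from"]
            for j, res in enumerate(chain):
                if j >= start:
                    res.seqid = gemmi.SeqId(res.seqid.num + 2, " ")
        if "drop_atom" in damage:
            ridx, aname = damage["drop_atom"]
            res = chain[ridx]
            for ai in range(len(res) - 1, -1, -1):
                if res[ai].name == aname:
                    del res[ai]
        if "rename_residue" in damage:
            ridx, newname = damage["rename_residue"]
            chain[ridx].name = newname
        emit(st, 0.25)

    # nonprotein: a chain holding only a ligand residue
    st = gemmi.Structure()
    st.resolution = 2.0
    st.raw_remarks = ["REMARK   2 RESOLUTION.    2.00 ANGSTROMS."]
    st.info["_exptl.method"] = "X-RAY DIFFRACTION"
    st.info["_struct_keywords.text"] = "SYNTHETIC FIXTURE"
    model = gemmi.Model("1")
    ch = gemmi.Chain("A")
    res = gemmi.Residue()
    res.name = "LIG"
    res.seqid = gemmi.SeqId(1, " ")
    res.het_flag = "H"
    for j, nm in enumerate(("C1", "C2", "O1")):
        a = gemmi.Atom()
        a.name = nm
        a.element = gemmi.Element(nm[0])
        a.pos = gemmi.Position(float(j), 0.0, 0.0)
        a.occ = 1.0
        a.b_iso = 30.0
        res.add_atom(a)
    ch.add_residue(res)
    model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    emit(st, 0.25)

    # too_short: a single-residue protein chain
    short = generate_backbone(2, geom, seed=seed + 4, entry_id="TMP", chain_id="A")
    st = to_gemmi_structure([short], "TMP", resolution=2.0, r_free=0.25)
    del st[0]["A"][1]
    emit(st, 0.25)
    return idx


def emit_corpus(spec: FixtureSpec, out_dir: str | Path) -> tuple[list[Path], GroundTruth]:
    """Write a synthetic corpus (PDB under ``pdb/``, mmCIF twins under
    ``mmcif/``) plus ``ground_truth.json``; returns paths and ground truth.

    Base chains get per-chain twist jitter so equal-length chains are far
    apart; planted duplicates are derived from the first base chains in a
    fixed category cycle.  Deterministic: same spec (incl. seed) ⇒
    byte-identical files.
    """
    out_dir = Path(out_dir)
    out_pdb = out_dir / "pdb"
    out_cif = out_dir / "mmcif"
    out_pdb.mkdir(parents=True, exist_ok=True)
    out_cif.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    truth = GroundTruth()
    paths: list[Path] = []
    idx = 1

    def meta():
        return (
            round(float(rng.uniform(1.2, 3.8)), 2),
            round(float(rng.uniform(0.18, 0.32)), 4),
        )

    def emit(chains, group=False):
        nonlocal idx
        eid = f"s{idx:03d}"
        idx += 1
        resolution, r_free = meta()
        named = []
        for pos, bb in enumerate(chains):
            cid = chr(ord("A") + pos)
            named.append(bb.with_coords(bb.atoms(), entry_id=eid, chain_id=cid))
            named[-1].aa_codes = list(bb.aa_codes)
        st = to_gemmi_structure(named, eid, resolution=resolution, r_free=r_free,
                                group_deposition=group)
        p = out_pdb / f"{eid}.pdb"
        write_entry(st, p, out_cif / f"{eid}.cif", r_free=r_free)
        paths.append(p)
        return eid, [c.chain_id for c in named]

    def snapped(bb: BackboneChain) -> BackboneChain:
        # PDB serializes at 3 decimals; snapping first keeps planted
        # deviations exact through file round-trips
        return bb.with_coords(np.round(bb.atoms(), 3))

    # base chains, each its own entry
    base = []
    for i in range(spec.n_chains):
        m = int(rng.integers(lo, hi + 1))
        geom = HelixGeometry(
            bond_n_ca=spec.geometry.bond_n_ca,
            bond_ca_c=spec.geometry.bond_ca_c,
            angle_n_ca_c=spec.geometry.angle_n_ca_c,
            twist=spec.geometry.twist + float(rng.uniform(-25.0, 25.0)),
            rise=spec.geometry.rise + float(rng.uniform(-0.3, 0.3)),
            radius=spec.geometry.radius,
        )
        bb = snapped(generate_backbone(m, geom, seed=int(rng.integers(2**31)), entry_id="TMP"))
        eid, cids = emit([bb])
        base.append(bb.with_coords(bb.atoms(), entry_id=eid, chain_id=cids[0]))

    # planted duplicates and decoys, cycling over base chains
    plan = (
        [("exact", True)] * spec.n_exact
        + [("perturbed", True)] * spec.n_perturbed
        + [("label_swap", True)] * spec.n_label_swap
        + [("rigid_copy", True)] * spec.n_rigid_copy
        + [("mirror", False)] * spec.n_mirror
        + [("far_perturbed", False)] * spec.n_far_perturbed
    )
    shift_step = max(round(spec.delta, 3), 0.001)
    for j, (category, is_duplicate) in enumerate(plan):
        src = base[j % len(base)]
        dup_seed = int(rng.integers(2**31))
        if category == "exact":
            dup = make_duplicate(src, "exact", seed=dup_seed)
        elif category == "perturbed":
            # uniform mÅ shift along one axis: the offset real
            # near-duplicate redepositions exhibit; rigid, hence invisible
            # to the invariant, but visible as max_dev in the report
            axis = int(rng.integers(3))
            shift = np.zeros(3)
            shift[axis] = shift_step * (1 if rng.integers(2) else -1)
            dup = src.with_coords(src.atoms() + shift, entry_id=src.entry_id + "d")
        elif category == "label_swap":
            k = min(spec.label_swap_k, src.m)
            dup = make_duplicate(src, "label_swap", k=k, seed=dup_seed)
        elif category == "rigid_copy":
            dup = src.with_coords(
                grid_rigid_motion(np.random.default_rng(dup_seed)).apply(src.atoms()),
                entry_id=src.entry_id + "d",
            )
        elif category == "mirror":
            dup = src.with_coords(-src.atoms(), entry_id=src.entry_id + "d")
        else:  # far_perturbed
            dup = snapped(
                make_duplicate(src, "perturb", delta=spec.far_delta, seed=dup_seed)
            )
        eid, cids = emit([dup])
        if not is_duplicate:
            truth.decoys.append(eid)
        else:
            dev = (
                float(np.max(np.linalg.norm(dup.atoms() - src.atoms(), axis=1)))
                if category != "rigid_copy"
                else 0.0
            )
            truth.pairs.append(
                PlantedPair(src.entry_id, src.chain_id, eid, cids[0], category, dev)
            )

    if spec.include_same_entry_pair:
        src = base[0]
        twin = make_duplicate(src, "exact", seed=int(rng.integers(2**31)))
        emit([src, twin])

    if spec.include_group_deposition:
        src = base[-1]
        dup = src.with_coords(
            grid_rigid_motion(np.random.default_rng(int(rng.integers(2**31)))).apply(src.atoms()),
            entry_id=src.entry_id + "g",
        )
        eid, _ = emit([dup], group=True)
        truth.decoys.append(eid)

    if spec.include_filter_violations:
        _write_violation_entries(out_pdb, out_cif, spec.geometry, spec.seed + 1000, 1)

    truth.to_json(out_dir / "ground_truth.json")
    return paths, truth
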