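"""Reading PDB/mmCIF entries and cleaning chains for invariant computation.

Parsing stands on :mod:`gemmi`.  The cleaning step mirrors the corpus
preparation used for duplicate scanning of crystal structures: a chain is
usable only when its main-chain trace is unambiguous — full occupancies,
no alternate conformations, consecutive residue numbering without
insertion codes, all of N/Cα/C present for every residue, and only the 20
canonical amino acids.  Chains whose only incomplete residues sit at the
termini are trimmed rather than discarded.  Every decision is recorded in
a :class:`FilterReport` so corpus-level rejection counts are auditable.
"""

from __future__ import annotations

import gzip
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .errors import MissingResolution, ParseError, UnsupportedFormat
from .invariant import BackboneChain

log = logging.getLogger(__name__)

#: canonical 3-letter -> 1-letter amino-acid codes (MSE etc. are nonstandard)
STANDARD_AA = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

_WATER_NAMES = {"HOH", "DOD", "WAT"}

MAINCHAIN_ATOMS = ("N", "CA", "C")

#: FilterReport categories, in the order rules are applied
CATEGORIES = (
    "nonprotein",
    "partial_occupancy",
    "nonconsecutive_numbering",
    "missing_mainchain",
    "nonstandard_residue",
    "too_short",
)


@dataclass
class RawAtom:
    name: str
    element: str
    pos: tuple[float, float, float]
    occupancy: float
    b_factor: float
    altloc: str


@dataclass
class RawResidue:
    name: str
    number: int
    insertion_code: str
    atoms: list[RawAtom]

    def atom(self, name: str) -> RawAtom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def has_mainchain(self) -> bool:
        return all(self.atom(n) is not None for n in MAINCHAIN_ATOMS)


@dataclass
class RawChain:
    chain_id: str
    residues: list[RawResidue]


@dataclass
class StructureRecord:
    """One parsed deposition: raw chains plus the header metadata used for scoping."""

    entry_id: str
    chains: list[RawChain]
    resolution: float | None = None
    r_free: float | None = None
    method: str = ""
    title: str = ""
    keywords: str = ""
    group_deposition: bool = False


@dataclass
class FilterPolicy:
    """Knobs of the chain-cleaning and scoping rules."""

    max_resolution: float = 4.0
    min_residues: int = 2
    #: restrict the occupancy/altloc rule to main-chain atoms only
    occupancy_mainchain_only: bool = False
    #: additionally require the carbonyl O for residue completeness
    require_carbonyl_o: bool = False
    #: residue names accepted beyond the canonical 20 (e.g. {"MSE": "M"})
    extra_standard_residues: dict = field(default_factory=dict)

    def standard_aa(self) -> dict:
        d = dict(STANDARD_AA)
        d.update(self.extra_standard_residues)
        return d


@dataclass
class ChainOutcome:
    entry_id: str
    chain_id: str
    status: str               # kept | rejected | trimmed
    category: str | None = None
    n_kept: int = 0
    n_removed_front: int = 0
    n_removed_back: int = 0


@dataclass
class FilterReport:
    """Per-chain outcomes plus per-category counts; counts sum to #chains."""

    outcomes: list[ChainOutcome] = field(default_factory=list)

    @property
    def counts(self) -> dict:
        c = {"kept": 0, "trimmed": 0}
        c.update({cat: 0 for cat in CATEGORIES})
        for o in self.outcomes:
            if o.status == "rejected":
                c[o.category] += 1
            else:
                c[o.status] += 1
        return c

    def extend(self, other: "FilterReport") -> None:
        self.outcomes.extend(other.outcomes)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "counts": self.counts,
            "n_chains": len(self.outcomes),
            "chains": [vars(o) for o in self.outcomes],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_table(self) -> str:
        header = f"{'entry':8s} {'chain':5s} {'status':9s} {'category':24s} {'kept':>5s} {'trim':>9s}"
        lines = [header, "-" * len(header)]
        for o in self.outcomes:
            trim = f"{o.n_removed_front}+{o.n_removed_back}" if o.status == "trimmed" else ""
            lines.append(
                f"{o.entry_id:8s} {o.chain_id:5s} {o.status:9s} "
                f"{o.category or '':24s} {o.n_kept:5d} {trim:>9s}"
            )
        counts = self.counts
        lines.append("-" * len(header))
        lines.append("totals: " + ", ".join(f"{k}={v}" for k, v in counts.items() if v))
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# reading

_RFREE_RE = re.compile(r"FREE R VALUE\s*(?:\(NO CUTOFF\))?\s*:\s*([0-9.]+)")


def _detect_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".gz"):
        name = name[:-3]
    if name.endswith((".pdb", ".ent")):
        return "pdb"
    if name.endswith((".cif", ".mmcif")):
        return "mmcif"
    raise UnsupportedFormat(f"cannot infer format of {path}")


def _read_text(path: Path) -> str:
    if path.name.endswith(".gz"):
        with gzip.open(path, "rt") as fh:
            return fh.read()
    return path.read_text()


def _validate_pdb_coordinates(text: str, path) -> None:
    # gemmi tolerates garbage in the fixed-width coordinate columns; fail
    # loudly instead, naming the offending line
    for lineno, line in enumerate(text.splitlines(), 1):
        if line.startswith(("ATOM  ", "HETATM")):
            for sl in (slice(30, 38), slice(38, 46), slice(46, 54)):
                fieldtext = line[sl].strip()
                try:
                    float(fieldtext)
                except ValueError:
                    raise ParseError(
                        f"{path}: line {lineno}: malformed coordinate field {fieldtext!r}"
                    ) from None


def read_structure(path: str | Path, fmt: str = "auto") -> StructureRecord:
    """Parse a PDB or mmCIF file (first model only) into a StructureRecord.

    ``fmt`` is ``pdb``, ``mmcif`` or ``auto`` (infer from the extension;
    ``.gz`` is transparently decompressed).
    """
    path = Path(path)
    if fmt == "auto":
        fmt = _detect_format(path)
    if fmt not in ("pdb", "mmcif"):
        raise UnsupportedFormat(f"unknown format {fmt!r}")
    text = _read_text(path)
    r_free = None
    try:
        if fmt == "pdb":
            _validate_pdb_coordinates(text, path)
            st = gemmi.read_pdb_string(text)
            for line in st.raw_remarks:
                mm = _RFREE_RE.search(line)
                if mm:
                    r_free = float(mm.group(1))
                    break
        else:
            block = gemmi.cif.read_string(text).sole_block()
            st = gemmi.make_structure_from_block(block)
            v = block.find_value("_refine.ls_R_factor_R_free")
            if v not in (None, ".", "?"):
                r_free = float(v)
            if st.resolution == 0.0:
                for tag in ("_refine.ls_d_res_high", "_reflns.d_resolution_high"):
                    v = block.find_value(tag)
                    if v not in (None, ".", "?"):
                        st.resolution = float(v)
                        break
    except (RuntimeError, ValueError) as err:
        raise ParseError(f"{path}: {err}") from err

    st.remove_waters()
    info = dict(st.info)
    keywords = info.get("_struct_keywords.text", "") or ""
    title = info.get("_struct.title", "") or ""
    group = "GROUP DEPOSITION" in (keywords + " " + title).upper()
    entry_id = (info.get("_entry.id") or st.name or path.stem).lower()

    chains: list[RawChain] = []
    if len(st) > 0:
        model = st[0]
        for ch in model:
            residues = []
            for res in ch:
                atoms = [
                    RawAtom(
                        name=a.name,
                        element=a.element.name,
                        pos=(a.pos.x, a.pos.y, a.pos.z),
                        occupancy=a.occ,
                        b_factor=a.b_iso,
                        altloc=a.altloc if a.altloc != "\x00" else "",
                    )
                    for a in res
                ]
                for a in atoms:
                    if not all(np.isfinite(a.pos)):
                        raise ParseError(f"{path}: non-finite coordinate in {ch.name} {res.seqid.num}")
                residues.append(
                    RawResidue(
                        name=res.name,
                        number=res.seqid.num,
                        insertion_code=(res.seqid.icode or "").strip(),
                        atoms=atoms,
                    )
                )
            chains.append(RawChain(chain_id=ch.name, residues=residues))

    return StructureRecord(
        entry_id=entry_id,
        chains=chains,
        resolution=st.resolution if st.resolution > 0 else None,
        r_free=r_free,
        method=info.get("_exptl.method", "") or "",
        title=title,
        keywords=keywords,
        group_deposition=group,
    )


# ---------------------------------------------------------------------------
# cleaning

def _classify_chain(chain: RawChain, policy: FilterPolicy):
    """Apply the cleaning rules; return (category|None, residues, front, back)."""
    aa_map = policy.standard_aa()
    residues = [r for r in chain.residues if r.name not in _WATER_NAMES]

    # (a) nonprotein: no standard amino acid at all
    if not any(r.name in aa_map for r in residues):
        return "nonprotein", [], 0, 0

    # (b) partial occupancy / alternate conformations anywhere in the chain
    for r in residues:
        atoms = r.atoms
        if policy.occupancy_mainchain_only:
            atoms = [a for a in atoms if a.name in MAINCHAIN_ATOMS]
        for a in atoms:
            if a.occupancy < 1.0 - 1e-6 or a.altloc:
                return "partial_occupancy", [], 0, 0

    # (c) numbering: consecutive integers, no insertion codes
    if any(r.insertion_code for r in residues):
        return "nonconsecutive_numbering", [], 0, 0
    numbers = [r.number for r in residues]
    if any(b - a != 1 for a, b in zip(numbers, numbers[1:])):
        return "nonconsecutive_numbering", [], 0, 0

    # (d) main-chain completeness; terminal incompleteness is trimmed
    required = MAINCHAIN_ATOMS + (("O",) if policy.require_carbonyl_o else ())

    def complete(r: RawResidue) -> bool:
        return all(r.atom(n) is not None for n in required)

    first = 0
    last = len(residues)
    while first < last and not complete(residues[first]):
        first += 1
    while last > first and not complete(residues[last - 1]):
        last -= 1
    kept = residues[first:last]
    if any(not complete(r) for r in kept):
        return "missing_mainchain", [], 0, 0
    for r in kept:
        if r.atom("O") is None and not policy.require_carbonyl_o:
            log.debug("residue %s %d lacks carbonyl O (kept)", r.name, r.number)

    # (e) nonstandard amino acids
    if any(r.name not in aa_map for r in kept):
        return "nonstandard_residue", [], 0, 0

    # (f) minimum length after trimming
    if len(kept) < policy.min_residues:
        return "too_short", [], 0, 0

    return None, kept, first, len(residues) - last


def clean_chains(
    record: StructureRecord, policy: FilterPolicy | None = None
) -> tuple[list[BackboneChain], FilterReport]:
    """Extract usable backbone chains from a parsed entry.

    Problems never raise: each chain is either kept (possibly trimmed at
    the termini) or rejected under exactly one category of the report.
    """
    policy = policy or FilterPolicy()
    aa_map = policy.standard_aa()
    report = FilterReport()
    kept_chains: list[BackboneChain] = []
    for chain in record.chains:
        category, residues, front, back = _classify_chain(chain, policy)
        if category is not None:
            report.outcomes.append(
                ChainOutcome(record.entry_id, chain.chain_id, "rejected", category)
            )
            continue
        coords = {
            name: np.array([r.atom(name).pos for r in residues])
            for name in MAINCHAIN_ATOMS
        }
        bb = BackboneChain(
            entry_id=record.entry_id,
            chain_id=chain.chain_id,
            residue_numbers=[r.number for r in residues],
            aa_codes=[aa_map[r.name] for r in residues],
            n=coords["N"], ca=coords["CA"], c=coords["C"],
        )
        kept_chains.append(bb)
        status = "trimmed" if (front or back) else "kept"
        report.outcomes.append(
            ChainOutcome(
                record.entry_id, chain.chain_id, status,
                n_kept=len(residues), n_removed_front=front, n_removed_back=back,
            )
        )
    return kept_chains, report


def in_scope(record: StructureRecord, policy: FilterPolicy | None = None) -> bool:
    """Scoping rule: resolution within the cut-off and not a group deposition.

    Entries without a resolution are out of scope (logged as a warning) —
    scanning targets crystal structures where the resolution is reported.
    """
    policy = policy or FilterPolicy()
    if record.group_deposition:
        return False
    if record.resolution is None:
        log.warning("%s: no resolution in header; treated as out of scope", record.entry_id)
        return False
    return record.resolution <= policy.max_resolution
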