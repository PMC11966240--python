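"""Parsing PDB/mmCIF entries and the chain-cleaning filter rules."""

import gzip

import numpy as np
import pytest

from dupscan import (
    FilterPolicy,
    ParseError,
    UnsupportedFormat,
    bri_distance,
    clean_chains,
    compute_bri,
    generate_backbone,
    in_scope,
    read_structure,
)
from dupscan.fixtures import to_gemmi_structure, write_entry
from dupscan.structure_io import StructureRecord, RawChain, RawResidue, RawAtom


def _atom_line(serial, name, resname, chain, resnum, x, y, z, occ=1.0, b=20.0,
               altloc=" ", icode=" ", element=None):
    element = element or name[0]
    return (
        f"ATOM  {serial:5d} {name:^4s}{altloc}{resname:3s} {chain}{resnum:4d}{icode}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {element:>2s}"
    )


def _chain_pdb(residues, header=True):
    """residues: list of (resname, resnum, atoms) where atoms is a list of
    (name, x, y, z) or (name, x, y, z, occ) or dict extras."""
    lines = []
    if header:
        lines += [
            "HEADER    HYDROLASE                               01-JAN-20   1ABC",
            "REMARK   2 RESOLUTION.    2.20 ANGSTROMS.",
            "REMARK   3   FREE R VALUE                     : 0.245",
        ]
    serial = 1
    for resname, resnum, atoms, *extra in residues:
        kw = extra[0] if extra else {}
        for a in atoms:
            name, x, y, z = a[0], a[1], a[2], a[3]
            occ = a[4] if len(a) > 4 else 1.0
            lines.append(
                _atom_line(serial, name, resname, "A", resnum, x, y, z, occ=occ, **kw)
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def _ideal_residues(m, start=1, resname="ALA"):
    """m clean residues along x with ideal local geometry."""
    out = []
    for i in range(m):
        x0 = 3.0 * i
        out.append(
            (resname, start + i, [
                ("N", 1.458 + x0, 0.0, 0.0),
                ("CA", x0, 0.0, 0.0),
                ("C", -0.551 + x0, 1.422, 0.0),
                ("O", -1.2 + x0, 2.1, 0.0),
            ])
        )
    return out


class TestReadStructure:
    def test_minimal_two_residue_fixture(self, tmp_path):
        p = tmp_path / "mini.pdb"
        p.write_text(_chain_pdb(_ideal_residues(2)))
        rec = read_structure(p)
        assert rec.entry_id == "1abc"
        assert len(rec.chains) == 1
        assert sum(len(r.atoms) for r in rec.chains[0].residues) == 8
        assert rec.resolution == pytest.approx(2.2)
        assert rec.r_free == pytest.approx(0.245)

    def test_pdb_and_mmcif_dialects_agree(self, tmp_path):
        chain = generate_backbone(12, seed=5, entry_id="syn1")
        st = to_gemmi_structure([chain], "syn1", resolution=1.9, r_free=0.21)
        write_entry(st, tmp_path / "e.pdb", tmp_path / "e.cif", r_free=0.21)
        rec_pdb = read_structure(tmp_path / "e.pdb")
        rec_cif = read_structure(tmp_path / "e.cif")
        assert rec_pdb.entry_id == rec_cif.entry_id
        assert rec_pdb.resolution == pytest.approx(rec_cif.resolution)
        assert rec_pdb.r_free == pytest.approx(rec_cif.r_free)
        chains_pdb, _ = clean_chains(rec_pdb)
        chains_cif, _ = clean_chains(rec_cif)
        assert len(chains_pdb) == len(chains_cif) == 1
        a, b = chains_pdb[0], chains_cif[0]
        assert a.aa_codes == b.aa_codes
        assert list(a.residue_numbers) == list(b.residue_numbers)
        # PDB quantizes to 3 decimals; both dialects must agree on those values
        np.testing.assert_allclose(a.atoms(), b.atoms(), atol=5.1e-4)
        q = a.with_coords(np.round(a.atoms(), 3))
        r = b.with_coords(np.round(b.atoms(), 3))
        assert bri_distance(compute_bri(q), compute_bri(r)) == 0.0

    def test_malformed_coordinate_names_line(self, tmp_path):
        text = _chain_pdb(_ideal_residues(2))
        text = text.replace("   1.458", "   1.4x8", 1)
        p = tmp_path / "bad.pdb"
        p.write_text(text)
        with pytest.raises(ParseError, match=r"line 4"):
            read_structure(p)

    def test_gzip_transparent(self, tmp_path):
        p = tmp_path / "mini.pdb.gz"
        with gzip.open(p, "wt") as fh:
            fh.write(_chain_pdb(_ideal_residues(3)))
        rec = read_structure(p)
        assert len(rec.chains[0].residues) == 3

    def test_unknown_extension(self, tmp_path):
        p = tmp_path / "mini.xyz"
        p.write_text("")
        with pytest.raises(UnsupportedFormat):
            read_structure(p)


def _record(residues):
    """Wrap handcrafted raw residues in a StructureRecord."""
    return StructureRecord(entry_id="test", chains=[RawChain("A", residues)])


def _raw_residue(resname, num, atom_names=("N", "CA", "C", "O"), occ=1.0,
                 altloc="", icode=""):
    atoms = [
        RawAtom(n, n[0], (float(i), 0.4 * (i % 2) + float(num), 0.0), occ, 20.0, altloc)
        for i, n in enumerate(atom_names)
    ]
    return RawResidue(resname, num, icode, atoms)


class TestCleanChains:
    def test_clean_chain_kept_and_idempotent(self, tmp_path):
        p = tmp_path / "ok.pdb"
        p.write_text(_chain_pdb(_ideal_residues(10)))
        chains, report = clean_chains(read_structure(p))
        assert len(chains) == 1 and chains[0].m == 10
        assert report.counts["kept"] == 1
        assert sum(report.counts.values()) == 1

    def test_partial_occupancy_rejected(self):
        residues = [_raw_residue("ALA", i) for i in range(1, 6)]
        residues[2].atoms[1].occupancy = 0.5
        _, report = clean_chains(_record(residues))
        assert report.counts["partial_occupancy"] == 1

    def test_altloc_rejected(self):
        residues = [_raw_residue("ALA", i) for i in range(1, 6)]
        residues[0].atoms[0].altloc = "A"
        _, report = clean_chains(_record(residues))
        assert report.counts["partial_occupancy"] == 1

    def test_sidechain_occupancy_ignored_with_mainchain_policy(self):
        residues = [_raw_residue("ALA", i, atom_names=("N", "CA", "C", "O", "CB"))
                    for i in range(1, 6)]
        residues[2].atoms[4].occupancy = 0.5   # CB only
        chains, report = clean_chains(
            _record(residues), FilterPolicy(occupancy_mainchain_only=True)
        )
        assert len(chains) == 1
        _, strict = clean_chains(_record(residues))
        assert strict.counts["partial_occupancy"] == 1

    def test_gap_in_numbering_rejected(self):
        residues = [_raw_residue("ALA", n) for n in (1, 2, 4, 5)]
        _, report = clean_chains(_record(residues))
        assert report.counts["nonconsecutive_numbering"] == 1

    def test_insertion_code_rejected(self):
        residues = [_raw_residue("ALA", i) for i in range(1, 5)]
        residues[1].insertion_code = "A"
        _, report = clean_chains(_record(residues))
        assert report.counts["nonconsecutive_numbering"] == 1

    def test_leading_incomplete_residue_trimmed(self):
        residues = [_raw_residue("ALA", 1, atom_names=("CA", "C", "O"))] + [
            _raw_residue("ALA", i) for i in range(2, 11)
        ]
        chains, report = clean_chains(_record(residues))
        assert len(chains) == 1 and chains[0].m == 9
        out = report.outcomes[0]
        assert out.status == "trimmed"
        assert (out.n_removed_front, out.n_removed_back) == (1, 0)

    def test_interior_incomplete_residue_rejected(self):
        residues = [_raw_residue("ALA", i) for i in range(1, 11)]
        residues[5].atoms = [a for a in residues[5].atoms if a.name != "N"]
        _, report = clean_chains(_record(residues))
        assert report.counts["missing_mainchain"] == 1

    def test_missing_carbonyl_o_kept_by_default(self):
        residues = [_raw_residue("ALA", i, atom_names=("N", "CA", "C"))
                    for i in range(1, 6)]
        chains, _ = clean_chains(_record(residues))
        assert len(chains) == 1
        _, report = clean_chains(_record(residues), FilterPolicy(require_carbonyl_o=True))
        assert report.counts["too_short"] == 1   # every residue incomplete -> all trimmed

    def test_nonstandard_residue_rejected_and_overridable(self):
        residues = [_raw_residue("ALA", i) for i in range(1, 6)]
        residues[2].name = "MSE"
        _, report = clean_chains(_record(residues))
        assert report.counts["nonstandard_residue"] == 1
        chains, _ = clean_chains(
            _record(residues), FilterPolicy(extra_standard_residues={"MSE": "M"})
        )
        assert len(chains) == 1 and chains[0].aa_codes[2] == "M"

    def test_nonprotein_chain(self):
        residues = [RawResidue("LIG", 1, "", [RawAtom("C1", "C", (0, 0, 0), 1.0, 20.0, "")])]
        _, report = clean_chains(_record(residues))
        assert report.counts["nonprotein"] == 1

    def test_too_short(self):
        _, report = clean_chains(_record([_raw_residue("ALA", 1)]))
        assert report.counts["too_short"] == 1

    def test_conservation_every_chain_accounted_once(self):
        rec = StructureRecord(
            entry_id="multi",
            chains=[
                RawChain("A", [_raw_residue("ALA", i) for i in range(1, 6)]),
                RawChain("B", [_raw_residue("ALA", n) for n in (1, 3)]),
                RawChain("C", [RawResidue("LIG", 1, "",
                                          [RawAtom("C1", "C", (0, 0, 0), 1.0, 20.0, "")])]),
            ],
        )
        _, report = clean_chains(rec)
        assert len(report.outcomes) == 3
        assert sum(report.counts.values()) == 3

    def test_report_serialization(self):
        residues = [_raw_residue("ALA", i) for i in range(1, 6)]
        _, report = clean_chains(_record(residues))
        text = report.to_json()
        assert '"kept": 1' in text
        assert "totals" in report.to_table()


class TestInScope:
    def _rec(self, resolution=None, group=False):
        return StructureRecord("x", [], resolution=resolution, group_deposition=group)

    def test_good_resolution(self):
        assert in_scope(self._rec(resolution=2.2)) is True

    def test_resolution_too_low(self):
        assert in_scope(self._rec(resolution=4.5)) is False

    def test_boundary_inclusive(self):
        assert in_scope(self._rec(resolution=4.0)) is True

    def test_group_deposition_excluded(self):
        assert in_scope(self._rec(resolution=1.5, group=True)) is False

    def test_missing_resolution_out_of_scope(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="dupscan.structure_io"):
            assert in_scope(self._rec()) is False
        assert any("resolution" in r.message for r in caplog.records)
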