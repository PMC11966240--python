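"""End-to-end duplicate scan of a synthetic corpus.

Emits a small corpus of PDB files with planted duplicates (exact, mÅ
shifted, relabeled, rigid-motion copies) and decoys (mirror images,
heavily perturbed copies), scans it with the cascade, and prints the
report alongside the ground truth.
"""

import tempfile
from pathlib import Path

from dupscan import FixtureSpec, ScanConfig, emit_corpus, scan_directory

with tempfile.TemporaryDirectory() as tmp:
    spec = FixtureSpec(n_chains=8, seed=4, include_filter_violations=True)
    _, truth = emit_corpus(spec, tmp)
    result = scan_directory(Path(tmp) / "pdb", ScanConfig(threshold=0.01))

    print("planted duplicate pairs:")
    for p in truth.pairs:
        print(f"  {p.entry_id1} ~ {p.entry_id2}  ({p.category}, "
              f"planted max dev {p.planted_max_dev:.3f} Å)")
    print("decoy entries (must not be reported):", ", ".join(truth.decoys))

    print("\nchain-cleaning outcomes:",
          {k: v for k, v in result.filter_report.counts.items() if v})

    print(f"\nscan at t = 0.01 Å found {len(result.pairs)} pair(s):")
    for r in result.reports:
        print(f"  {r.entry_id1}:{r.chain_id1} ~ {r.entry_id2}:{r.chain_id2}  "
              f"m={r.n_residues}  d_bri={r.d_bri:.4f}  max_dev={r.max_dev:.3f}  "
              f"n_diff_res={r.n_diff_res}")
    print("-> every planted pair is recovered, every decoy rejected;")
    print("   max_dev and n_diff_res are the per-pair forensic statistics.")
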