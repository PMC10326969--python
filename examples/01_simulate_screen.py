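"""Simulate a small knockout screen and write it to TSV files.

Generates 40 synthetic target sites (random protospacers with an NGG PAM
in a shared construct context), draws multinomial read counts for a
control line and two knockouts, and writes the target library plus the
long-format counts table.
"""

from pathlib import Path

from cas9repair import GenerativeParams, generate_targets, sample_screen, write_dataset

out = Path("example_output")
out.mkdir(exist_ok=True)

params = GenerativeParams(n_targets=40, depth_median=1500)
targets = generate_targets(params, seed=1)
dataset, truth = sample_screen(targets, params, seed=2, lines=["control", "Nbn", "Lig4"])

write_dataset(dataset, out / "library.tsv", out / "counts.tsv")

n_outcomes = sum(len(p.counts) for p in dataset.profiles.values())
print(f"targets:          {len(dataset.targets)}")
print(f"samples:          {len(dataset.sample_keys)} (line x replicate x timepoint)")
print(f"count records:    {n_outcomes}")
print(f"written to:       {out}/library.tsv, {out}/counts.tsv")
# Each record is one (sample, target, outcome) read count; outcomes use the
# DEL:a-b / INS:pos:SEQ / IND:a-b:SEQ serialization in construct coordinates.
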