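"""Generate a synthetic FAERS drug corpus and standardize it end to end.

Builds a toy vocabulary and a 1,000-record drug file with planted ground
truth, runs the six-step mapping cascade plus ATC resolution, and prints
the coverage report. Coverage percentages are the fraction of drug
records (and of unique 7-field records) mapped to an ingredient-level
concept, and the fraction further resolved to a single ATC code.
"""

import tempfile
from pathlib import Path

from faersnorm import generate_faers_file, generate_vocabulary, run_pipeline
from faersnorm.report import format_coverage

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    ledger = generate_vocabulary(tmp / "vocab", seed=7)
    generate_faers_file(tmp / "drug.txt", 1000, ledger, seed=7,
                        gt_path=tmp / "ground_truth.tsv")
    stats = run_pipeline(tmp / "drug.txt", tmp / "vocab", tmp / "out")

print(format_coverage(stats))
print()
print("Every mapped record's audit trail is in out/mapping_table.tsv; the")
print("unmapped remainder is dominated by planted misspellings, which the")
print("exact-match cascade is designed not to rescue.")
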