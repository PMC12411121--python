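"""ATC resolution with route and strength evidence.

One active ingredient can hold several ATC codes split by therapeutic
use. The resolver assigns a code only when the record's evidence singles
out one crosswalk candidate; otherwise it abstains.
"""

import tempfile
from pathlib import Path

from faersnorm import DrugRecord, assign_atc, generate_vocabulary, load_vocab, map_record

with tempfile.TemporaryDirectory() as tmp:
    ledger = generate_vocabulary(Path(tmp) / "vocab", seed=1)
    index = load_vocab(Path(tmp) / "vocab")

    cases = [
        ("beta blocker by mouth", DrugRecord(drugname="TIMOLOL", route="ORAL")),
        ("same drug as eye drops", DrugRecord(drugname="TIMOLOL", route="OPHTHALMIC")),
        ("route unreported -> abstain", DrugRecord(drugname="TIMOLOL")),
        ("low-dose finasteride", DrugRecord(drugname="FINASTERIDE", dose_amt="1", dose_unit="MG")),
        ("high-dose finasteride", DrugRecord(drugname="FINASTERIDE", dose_amt="5", dose_unit="MG")),
        ("unspecific term -> abstain", DrugRecord(drugname="CALCIUM")),
    ]
    for label, record in cases:
        result = map_record(record, index)
        assign_atc(record, result, index)
        print(f"{label:32s} {record.drugname:12s} -> {result.atc_code}")

print()
print("A printed code means exactly one crosswalk entry was consistent with")
print("the ingredient plus the reported route/strength; None is a deliberate")
print("abstention, preferred over guessing among several plausible codes.")
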