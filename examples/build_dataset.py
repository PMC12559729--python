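"""Run the full pipeline on a synthetic fixture and write the dataset.

Generates a seeded fixture (three generic queries, a 24-compound candidate
library with planted match classes), runs query selection and expansion,
and writes the eight-column gzip CSV. The printed filter report uses the
same accounting as the selection filters: R-group presence first, then the
six-heavy-atom rule, then the biological-element policy.
"""

import json
import tempfile
from pathlib import Path

from biorgroup import ingest_library, read_dataset, run_pipeline, write_dataset
from biorgroup.fixtures import FixtureSpec, generate_fixture

workdir = Path(tempfile.mkdtemp())
fixture = generate_fixture(FixtureSpec(seed=11))
query_path = workdir / "queries.tsv"
fixture.write_query_tsv(query_path)

store, ingest_report = ingest_library(fixture.library)
print("ingest:", ingest_report.to_json())

result = run_pipeline(query_path, store)
print("filter report:", json.dumps(result.report.to_dict(), indent=2))

dataset_path = workdir / "biorgroup_demo.csv.gz"
digest = write_dataset(result.records, dataset_path)
print(f"wrote {len(result.records)} records to {dataset_path} (sha256 {digest[:12]}…)")

for record in read_dataset(dataset_path):
    print(
        f"  {record.smiles:>24s}  superstructures={len(record.core_superstructure_smiles)}"
        f"  extended={len(record.rgroup_extended_smiles)}"
    )
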