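"""Write a cohort to CSV, read it back, and apply the inclusion filter.

The study design requires at least three follow-ups with increasing volume;
the filter partitions any cohort into retained and excluded nodules with
per-nodule reasons.
"""

import tempfile
from pathlib import Path

from nodulegrowth import generate_fixture, inclusion_filter, read_cohort, write_cohort

cohort = generate_fixture("tiny")
with tempfile.TemporaryDirectory() as d:
    path = Path(d) / "tiny.csv"
    write_cohort(cohort, path)
    print(f"wrote {len(cohort)} nodules; first lines of {path.name}:")
    print("\n".join(path.read_text().splitlines()[:3]))
    back = read_cohort(path)

kept, log = inclusion_filter(back)
print(f"\nretained: {sorted(log.retained)}")
for nid, reason in sorted(log.excluded.items()):
    print(f"excluded: {nid} ({reason.value})")
# T006 shrinks between the first two scans, violating the increasing-volume
# criterion, so it is excluded with reason non_increasing.
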