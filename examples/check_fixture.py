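"""Verify the fixture cohort against its shipped manifest.

Rebuilds the cohort, re-derives every contractual marginal through the real
pipeline, and compares against the manifest (including the serialization
checksum).  All checks should pass; any failure names the violated count.
"""

from sarcphen import build_fixture_cohort, check_fixture

report = check_fixture(build_fixture_cohort())
print(f"{len(report.checks)} checks, all passed: {report.all_passed}")
for c in report.failures():
    print(f"  FAIL {c.name}: expected {c.expected}, observed {c.observed}")
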