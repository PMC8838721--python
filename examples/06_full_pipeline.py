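"""End-to-end run: synthesise a cohort, evaluate every participant-visit
and render the per-participant written reports."""
import tempfile
from pathlib import Path

from gfdeval.reporting import PipelineConfig, run_pipeline

out = Path(tempfile.mkdtemp(prefix="gfdeval_"))
result = run_pipeline(PipelineConfig(synth_seed=42, out_dir=str(out)))
print("counts:", result.counts)
print("outputs in:", out)
print()
print(result.reports[0].text)
# Each report lists nutritional status, diet quality and one advice line
# per flagged imbalance — the written feedback a participant receives
# after each visit.
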