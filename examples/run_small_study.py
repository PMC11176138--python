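"""Run a scaled-down end-to-end study and print its agreement table.

Six subjects instead of fifteen, otherwise the default design: both field
strengths, T2* and T2 mapping, pre/post contrast, duplicate acquisitions
and two simulated readers.  Each row of the printed table is one
repeatability (same reader, acquisition 1 vs 2) or reproducibility
(reader 1 vs 2, same acquisition) comparison pooled over field strength
and contrast state.
"""

from relaxrepro import StudyConfig, run_study, write_report

config = StudyConfig(n_subjects=6, base_seed=7)
outputs = run_study(config)

frame = outputs.report.to_frame()
print(frame[["label", "n", "ccc", "mean_diff_ms", "cov_percent", "cov_class"]]
      .to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print(f"\n{len(outputs.measurements)} measurements from "
      f"{config.n_subjects} subjects; files written:")
for path in write_report(outputs, "study_out_small"):
    print(" ", path)
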