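"""Two-method agreement analysis with a known proportional bias.

Simulates 500 trials measured by two methods that share the same angular
velocity but convert it to linear velocity with different effective radii
(2.20 m vs 2.05 m, ratio ~1.073), plus independent measurement noise, and
runs the full agreement battery.  Deming regression should flag the
proportional bias while the intercept stays near zero.
"""

from lpkin import agreement_report, simulate_paired_methods

pairs = simulate_paired_methods(500, seed=42)
report = agreement_report(pairs)

print(f"n = {report.n} paired trials ({report.indicator})")
print(f"Pearson r           : {report.pearson_r:.3f} ({report.pearson_band})")
print(f"bias (A - B)        : {report.bias:+.3f} m/s "
      f"[{report.bias_ci[0]:+.3f}, {report.bias_ci[1]:+.3f}]")
print(f"95% LoA             : [{report.loa_lower:+.3f}, {report.loa_upper:+.3f}] m/s")
print(f"paired t, p         : {report.t_stat:.2f}, {report.p_value:.4f}")
print(f"Cohen's d           : {report.cohens_d:.2f} ({report.cohens_d_band})")
print(f"Deming slope        : {report.deming_slope:.4f} "
      f"[{report.deming_slope_ci[0]:.4f}, {report.deming_slope_ci[1]:.4f}]")
print(f"Deming intercept    : {report.deming_intercept:+.4f} "
      f"[{report.deming_intercept_ci[0]:+.4f}, {report.deming_intercept_ci[1]:+.4f}]")
print(f"fixed bias flagged  : {report.fixed_bias}")
print(f"proportional bias   : {report.proportional_bias} "
      f"(true slope 2.20/2.05 = {2.20 / 2.05:.4f})")
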