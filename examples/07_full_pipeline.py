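"""The whole workflow in one call.

Runs the end-to-end pipeline on a simulated two-state scenario: buffer
subtraction, invariants, rigid-body template fit, conformer pools,
GA ensemble selection and Gaussian state decomposition, then prints the
report — the same table of numbers a SAXS study would publish per sample.
"""

import warnings

from confensa import run_pipeline

warnings.simplefilter("ignore")

report = run_pipeline({
    "condition": "apo (simulated two-state)",
    "seed": 4,
    "simulate": {"scenario": "apo_two_state", "params": {"f": 0.85}},
    "rigid_body": {"enabled": True},
    "ensemble": {"enabled": True, "n_members": 400, "generations": 200},
})

inv = report.invariants
print(f"condition        : {report.condition}")
print(f"Guinier Rg       : {inv['rg']:.1f} +- {inv['rg_err']:.1f} A")
print(f"Dmax             : {inv['dmax']:.0f} A")
print(f"MW (I0/Porod/Vc) : {inv['mw_i0_kda']:.0f} / {inv['mw_porod_kda']:.0f}"
      f" / {inv['mw_vc_kda']:.0f} kDa")
print(f"template fit     : chi2 = {report.rigid_body['chi2']:.2f}")
print(f"ensemble chi2    : {report.ensemble['chi2']:.2f}")
w = report.ensemble["pool_weights"]
print(f"pool weights     : compact {100 * w[0]:.0f}% / extended "
      f"{100 * w[1]:.0f}%   (planted 85/15)")
for pk in report.peaks:
    print(f"state peak       : Rg {pk['center_rg']:.1f} A "
          f"[FWHM {pk['fwhm']:.1f}] {{{pk['area_pct']:.0f}%}}")
if report.errors:
    print("stage errors     :", report.errors)
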