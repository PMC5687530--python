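"""Generate a noise-free phantom with prescribed disease burden and recover it.

Builds a deformation-free phantom with 15% emphysema and 25% air trapping in
every lobe, converts the HU volumes to air-fraction maps and measures Emph%
and fSAD% per lobe. On this phantom the measurements reproduce the
prescription exactly, which is the generator's core contract.
"""

from qctlung import (
    DeformationSpec,
    PhantomConfig,
    air_fraction,
    emphysema_percent,
    fsad_percent,
    generate_phantom_pair,
    warp_scalar,
)

cfg = PhantomConfig(
    target_emph_pct=15.0,
    target_fsad_pct=25.0,
    deformation_spec=DeformationSpec(),  # identity: exact-recovery regime
    noise_sd_hu=0.0,
    seed=1,
)
bundle = generate_phantom_pair(cfg)
refs = cfg.refs

beta_insp = air_fraction(bundle.tlc_volume, refs)
beta_exp = air_fraction(bundle.exp_volume, refs)
warped = warp_scalar(beta_insp, bundle.true_field)

emph = emphysema_percent(beta_insp, bundle.lobe_mask, refs)
fsad = fsad_percent(beta_exp, warped, bundle.lobe_mask, refs)

print("lobe     Emph%   fSAD%")
for lobe in bundle.lobe_mask.labels:
    print(f"{lobe:8s} {emph[lobe]:5.1f}   {fsad[lobe]:5.1f}")
print(f"{'lung':8s} {emph['whole_lung']:5.1f}   {fsad['whole_lung']:5.1f}")
print()
print("Each lobe was prescribed 15% emphysema (insp. beta_air > 0.985) and")
print("25% trapping (exp. beta_air > 0.90, not emphysematous at inspiration);")
print("the fraction-threshold measurements recover both exactly.")
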