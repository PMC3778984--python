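"""From raw rectified-EMG trials to recruitment curves and per-leg FCR.

One subject's TMS session holds, for each of the four stimulation
configurations (lesioned/contralesional cortex x paretic/non-paretic leg),
eight trials at each intensity from 100 to 150 %MT. Each trial is scored
as MEP area / pre-trigger area; block means form the recruitment curve,
whose fitted slope indexes corticospinal connectivity.
"""
import dataclasses

from fcrkit import (GeneratorConfig, generate_cohort, generate_emg_session,
                    session_curve_points, subject_fcr, subject_fits)

cfg = dataclasses.replace(GeneratorConfig(), n_subjects=3, seed=8)
state = generate_cohort(cfg)[0]
session = generate_emg_session(state, cfg)
print(f"session: {len(session)} trials "
      f"({cfg.trials_per_block} per block x {len(cfg.intensity_grid)} "
      f"intensities x 4 configurations)")

points = session_curve_points(session, cfg.mep_window, cfg.pre_trigger_window)
hemi, leg = "contralesional", "paretic"
print(f"\nrecruitment curve, stimulate {hemi} cortex -> record {leg} leg:")
for p in points[(hemi, leg)]:
    print(f"  {p.intensity:.0f} %MT -> normalized MEP {p.response:.3f} "
          f"({p.n_trials} trials)")

fits = subject_fits(session, cfg)
fcr = subject_fcr(fits)
for leg in ("paretic", "non-paretic"):
    r = fcr[leg]
    print(f"\n{leg}: ipsi slope {r.slope_ipsilateral:.4f}, "
          f"contra slope {r.slope_contralateral:.4f} per %MT point")
    print(f"  FCR = {r.fcr:.2f} -> {r.laterality}")
print("\n(The fitted slopes recover the generator's latent slopes; "
      "the FCR compares ipsilateral vs contralateral drive to each leg.)")
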