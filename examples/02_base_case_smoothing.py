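"""Simulate the base smoothing experiment and fit the smoothing time.

An undulated inoculum (wavelength 0.8 mm, amplitude 300 um) in the
intermediate porous medium (mean pore size 1.7 um) organizes into a
migrating front whose undulation amplitude decays exponentially.
Runs the desk-scale preset (a few minutes on one core).
"""

from chemosmooth import RunConfig, run_case

result = run_case(RunConfig())
s = result.summary()

print("undulation amplitude A(t) at the leading edge:")
for t, A in zip(result.trace.times[::3], result.trace.A[::3]):
    print(f"  t = {t / 3600:5.2f} hr   A = {A:6.1f} um")

print(f"\nsmoothing initiation  t0  = {s['t0_s'] / 3600:.2f} hr")
print(f"amplitude at t0       A0  = {s['A0_fit_um']:.0f} um")
print(f"smoothing time        tau = {s['tau_hr']:.2f} hr (exponential decay fit)")
print(f"catch-up time         tau' = {s['tau_prime_hr']:.2f} hr "
      "(valley-peak velocity gap integrated to A0)")
print(f"front speed (late)    {s['front_speed_um_per_s'] * 60:.1f} um/min")
print("\ntau and tau' agree within a factor of ~2: the amplitude decays on"
      "\nthe time scale set by valleys chemotactically catching up to peaks.")
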