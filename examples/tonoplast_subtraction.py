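"""Isolate the tonoplast action potential by trace arithmetic.

A vacuolar electrode records the series sum of the plasma-membrane and
tonoplast PDs.  This example builds two synthetic ensembles — plasma
membrane alone, and both membranes (plasma membrane plus a constructed
tonoplast component resting at +14 mV) — then recovers the tonoplast AP by
subtraction with standard deviations propagated in quadrature.
"""

import numpy as np

import characean_ap as ca

ps = ca.load_parameter_set(2, "AP_av Nitellopsis APW")

# six noisy plasma-membrane recordings
pm_traces = [ca.generate_recording(ps, noise_sd=2.0, sample_dt=0.01, seed=s)
             for s in range(6)]
pm = ca.average_traces(pm_traces)

# synthetic tonoplast component: +14 mV rest, transient to ~+120 mV
t = pm.t
tono_true = 14.0 + 106.0 * np.exp(-((t - 3.0) / 2.0) ** 2)

# seven noisy vacuolar (both-membranes) recordings = PM + tonoplast
rng = np.random.default_rng(99)
both_traces = [ca.Trace(t, pm_traces[s % 6].v[: len(t)] + tono_true
                        + rng.normal(0, 2.0, len(t)))
               for s in range(7)]
both = ca.average_traces(both_traces)

tono = ca.subtract_tonoplast(both, pm)
i_rest = t >= 15.0
print(f"tonoplast resting PD : {tono.mean[i_rest].mean():7.2f} mV (constructed: +14)")
print(f"tonoplast peak PD    : {tono.mean.max():7.2f} mV (constructed: +120)")
print(f"propagated SD (rest) : {np.nanmean(tono.sd[i_rest]):7.2f} mV "
      f"= sqrt(sd_both^2 + sd_pm^2)")

# a vacuolar record referenced to the bath is moved onto the tonoplast
# scale by adding back the approximate plasma-membrane PD
vac = ca.Trace(t, tono.mean - 55.0)
print(f"after +55 mV offset  : {ca.offset_trace(vac, 55.0).v[i_rest].mean():7.2f} mV "
      "(tonoplast scale recovered)")
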