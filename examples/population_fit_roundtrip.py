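"""Generate a synthetic cell population and recover its parameters.

Draws six virtual cells around the average fit (10% lognormal spread on the
key kinetic parameters, 1 mV recording noise), averages their APs the way a
multi-cell study would, and re-fits the store-pump rate p1' to the ensemble
mean — the full pipeline the package exists to test.
"""

import characean_ap as ca

base = ca.load_parameter_set(2, "AP_av Nitellopsis APW")
spec = ca.PopulationSpec(base=base, n_cells=6, noise_sd=1.0,
                         sample_dt=0.02, t_end=20.0, seed=7)
traces, truth = ca.generate_population(spec)
print("per-cell truth (lognormal draws around the base column):")
print(truth[["cell", "p1_prime", "p2_prime", "k_m3"]].round(4).to_string(index=False))

ens = ca.average_traces(traces)
fit_spec = ca.FitSpec(free={"p1_prime": (5.0, 15.0, 9.74 * 1.2)}, fixed=base)
result = ca.fit(ens.as_trace(), fit_spec)

true_p1 = base.kinetics.p1_prime
est = result.estimates["p1_prime"]
print(f"\nbase p1'     : {true_p1:.3f} uM/s")
print(f"recovered p1': {est:.3f} uM/s "
      f"({abs(est - true_p1) / true_p1 * 100:.1f}% off, "
      f"RMSE {result.loss:.2f} mV, {result.n_evals} simulations)")
print("Cell-to-cell spread plus averaging still returns the generating")
print("pump rate to within a few percent.")
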