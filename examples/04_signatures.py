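"""Refit mutational-signature weights to a 96-context spectrum.

Simulates 10,000 mutations from a known SBS1/SBS4 mixture, refits by
forward selection against the catalog, and prints the recovered weights.
"""

from mrith.signatures import refit_signatures, synthetic_catalog
from mrith.simulate import simulate_spectrum

catalog = synthetic_catalog()        # synthetic stand-in; swap a COSMIC TSV
truth = {"SBS1": 0.7, "SBS4": 0.3}
spectrum = simulate_spectrum(truth, n_mutations=10_000, catalog=catalog, seed=3)

fit = refit_signatures(spectrum, catalog)
print("true weights:      ", truth)
print("recovered weights: ", {k: round(v, 3) for k, v in fit.as_dict().items()})
print("residual SSE:      ", f"{fit.residual_sse:.2e}")
# Recovered weights land within a few hundredths of the generating mixture;
# components under the 6% cutoff are reported as zero.
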