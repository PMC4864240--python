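"""Competitive fluorescence assay: from displacement curves to a Ki table.

Simulates 1-NPN displacement curves for three protein-ligand pairs (one
strong binder, one moderate, one too weak to report), fits each curve,
converts IC50 to Ki with each protein's probe constant, and prints the
affinity table.  "u.d." marks pairs whose IC50 exceeds the 100 μM
reporting threshold — the assay's convention for "no measurable binding".
"""

from cspbind import (CompetitionConfig, affinity_from_fit,
                     build_affinity_table, fit_competition,
                     simulate_competition)

K_PROBE = {"CSP1": 11.66, "CSP2": 20.77, "CSP3": 15.32}  # μM, per protein

cases = [
    # protein, ligand, true Ki (μM), competitor range (μM)
    ("CSP1", "linoleic_acid", 5.719, (2.0, 50.0)),
    ("CSP3", "linoleic_acid", 42.86, (2.0, 400.0)),
    ("CSP2", "linoleic_acid", 150.0, (2.0, 400.0)),   # above threshold -> u.d.
]

results = []
for protein, ligand, ki_true, (lo, hi) in cases:
    series = simulate_competition(CompetitionConfig(
        ki=ki_true, k_probe=K_PROBE[protein], probe_conc=2.0,
        conc_min=lo, conc_max=hi, n_points=8, noise_sd=0.02,
        protein_id=protein, ligand_id=ligand, seed=42))
    fit = fit_competition(series)
    result = affinity_from_fit(series, fit, K_PROBE[protein])
    results.append(result)
    ic50 = f"{fit.ic50:.2f}" if fit.ic50 else "-"
    ki = f"{result.ki:.2f}" if result.ki else "-"
    print(f"{protein} + {ligand}: IC50 = {ic50} μM, Ki = {ki} μM "
          f"({fit.status}; true Ki {ki_true})")

print("\nAffinity table (Ki, μM; u.d. = IC50 > 100 μM):")
print(build_affinity_table(results))
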