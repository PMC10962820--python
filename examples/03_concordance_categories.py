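"""Compare treatment results against a disease-vs-control reference list.

Each protein lands in exactly one of six categories: opposite, equal,
treatment_only, disease_only, not_changed, unmatched. 'Opposite' proteins
move against their disease direction, i.e. treatment pushes them back
toward the control state.
"""

from deltaprot.compare import categorize
from deltaprot.discovery import run_discovery
from deltaprot.simulate import (
    SimulationConfig, assign_scheme, simulate_cohort, simulate_reference_diffset,
)

config = SimulationConfig(n_patients=40, n_proteins=200, frac_changed=0.4,
                          frac_immunoglobulin=0.0, noise_sd=0.15, seed=11)
manifest, table, keywords, truth = simulate_cohort(config)

scheme = assign_scheme(truth, n_per_category=10)  # known answer, 10 per category
reference = simulate_reference_diffset(truth, scheme)

records, _ = run_discovery(table, manifest, keywords)
assignments, summary = categorize(records, reference)

print("category counts (all quantified proteins):")
for cat, n in summary["category_counts"].items():
    print(f"  {cat:15s} {n}")
recovered = sum(assignments.loc[a, "category"] == c for a, c in scheme.items())
print(f"\nplanted 10-per-category scheme recovered: {recovered}/60")
# At the default noise level, nearly all planted labels are recovered; the
# remainder are proteins whose simulated effect fell short of FDR < 0.01.
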