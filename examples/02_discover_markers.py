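"""Discover consensus marker genes on a simulated reference panel.

Simulates three labeled datasets sharing 10 planted up-in-malignant and 15
planted up-in-non-malignant genes, runs per-dataset Wilcoxon differential
expression with the detection-fraction and fold-change filters, and
intersects the per-dataset calls into a consensus marker set.
"""

from precancell import (
    SimulationConfig,
    find_markers,
    intersect_markers,
    markers_to_frame,
    simulate_reference_panel,
)

cfg = SimulationConfig(
    n_malignant=150,
    n_non_malignant=150,
    n_genes=800,
    n_tmg_planted=10,
    n_nmg_planted=15,
    effect_size=2.0,
    seed=42,
)
panel = simulate_reference_panel(cfg, n_references=3)

tables = []
for member in panel:
    table = find_markers(member.dataset)
    n_dir = sum(m.direction.value != "none" for m in table)
    print(f"{member.dataset.name}: {n_dir} of {len(table)} genes called directional")
    tables.append((member.dataset.name, table))

consensus = intersect_markers(tables)
truth = set(panel[0].planted_tmg) | set(panel[0].planted_nmg)
recovered = len((set(consensus.tmg) | set(consensus.nmg)) & truth)
print(f"\nconsensus: {len(consensus.tmg)} TMGs + {len(consensus.nmg)} NMGs")
print(f"{recovered} of {len(truth)} planted markers recovered")
print("-> only genes up in the same direction in every dataset survive the intersection")

head = markers_to_frame(tables[0][1]).nsmallest(5, "p_adjusted")
print("\nstrongest calls in the first dataset:")
print(head.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
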