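"""Gated T-cell subset dynamics and per-subset proliferation rates.

Cells are gated by thresholds alone: Tcm = CD62L+CD27+, Tem = CD62L-CD27+,
Teff = CD62L-CD27-.  Although no cell carries a fate, the gated subsets
reproduce the published population dynamics: Tcm counts fall while Tem/Teff
rise, and from day 5 onward the Teff subset divides fastest.
"""

from cytonx import ModelConfig, division_events, simulate, subset_counts_by_day

config = ModelConfig(variant="heterogeneous_activation", seed=42)
pop = simulate(config)

counts = subset_counts_by_day(pop).pivot(index="day", columns="subset", values="count")
print("cells alive at the start of each day, by gated subset:")
print(counts[["Tcm", "Tem", "Teff", "other"]].to_string())

events = division_events(pop)
late = events[events["day"] >= 5]
rates = late.groupby("subset", observed=True)["rate"].mean()
print()
print("mean proliferation rate (1/h) of dividing cells, day 5 onward:")
for subset in ("Tcm", "Tem", "Teff"):
    print(f"  {subset:>4}: {rates[subset]:.4f}")
print()
print("Selection for fast-dividing lineages (which are also CD62L-low) makes")
print("the 'effector' gate look intrinsically faster — without any programmed")
print("difference between subsets.")
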