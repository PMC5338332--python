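"""Generate a small synthetic gonad small-RNA study and look at its truth.

Builds a reference (precursors with flanks, mature annotations, class
pools), draws negative-binomial counts for a 2-stage x 2-sex design and
emits adapter-ligated FASTQ libraries, all seeded.
"""

from gonadmir import simulate_counts, simulate_reads
from gonadmir.simdata import example_study

config, bundle, sheet = example_study(seed=1)
counts, truth = simulate_counts(config, sheet)
reads = simulate_reads(bundle, counts, config, truth)

print(f"{len(bundle.matures)} mature miRNAs, {len(sheet)} libraries")
print(f"reads in {sheet.index[0]}: {len(reads[sheet.index[0]])}")
print("\nplanted class mix (identical in every library):")
print(truth.class_fractions().iloc[:, 0].round(3).to_string())
print("\nplanted isomiR proportions:")
for mid, prof in truth.isomir_proportions.items():
    for key, p in prof.items():
        print(f"  {mid:22s} {key:12s} {p:.2f}")
# Each library is ~10k reads; class fractions are the planted mix and the
# isomiR table is the per-variant multinomial probability, canonical included.
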