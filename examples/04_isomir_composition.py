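"""Summarize isomiR composition per group and track a substitution.

The three most abundant matures carry planted variant profiles
(templated +1, untemplated +1U with a 5' truncation, and a terminal
substitution); the per-group tables recover them.
"""

from gonadmir import simulate_counts, simulate_reads, quantify_samples
from gonadmir import substitution_dynamics, summarize_isomirs
from gonadmir.simdata import example_study

config, bundle, sheet = example_study(seed=1)
counts, truth = simulate_counts(config, sheet)
reads = simulate_reads(bundle, counts, config, truth)
result = quantify_samples(reads, bundle, sheet, config.adapter)

table = summarize_isomirs(result.isomir_calls, sheet["group"].to_dict(),
                          min_fraction=0.05)
planted = set(truth.isomir_proportions)
view = table.filtered
print("variants at >= 5% of a miRNA's reads (planted matures, one group):")
one_group = view[(view["group"] == "testis_6") & view["mature_id"].isin(planted)]
print(one_group.to_string(index=False,
                          formatters={"fraction": "{:.3f}".format}))

sub_mature, sub_key = next(
    (m, k) for m, prof in truth.isomir_proportions.items()
    for k in prof if "!" in k
)
from_base, to_base = sub_key.split(":")[1].rstrip("!").split(">")
series = substitution_dynamics(table, from_base, to_base,
                               mature_ids=[sub_mature])
print(f"\nterminal {from_base}>{to_base} fraction for {sub_mature} "
      f"per group (planted 0.25):")
print(series.to_string(index=False, formatters={"fraction": "{:.3f}".format}))
# Recovered fractions sit within multinomial sampling error of the planted
# proportions; keys ending in '*' are untemplated additions, '!' marks a
# substitution at the 3'-terminal base.
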