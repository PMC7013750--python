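"""Reproduce the published response-classification arithmetic.

Runs the temporal (75 s rocket hypergravity x 300 s centrifuge
hypergravity) and the flight-microgravity x vector-averaged-gravity
classifiers over the published cross-tabulated transcript-cluster counts
and prints the resulting class totals and percentages.
"""

from gravicomp import datasets
from gravicomp.classify import (
    classify_counts,
    classify_cross_microgravity,
    classify_temporal,
    round_percent,
)

for name, data, classifier in (
    ("temporal (75 s vs 300 s hypergravity)",
     datasets.temporal_crosstab(), classify_temporal),
    ("flight microgravity vs vag",
     datasets.cross_microgravity_crosstab(), classify_cross_microgravity),
):
    totals = classify_counts(data["cells"], classifier,
                             eliminated=data["eliminated"])
    print(f"{name} — universe {data['universe']} TCs")
    for label, count in sorted(totals.items(), key=lambda kv: -kv[1]):
        print(f"  {label:<16}{count:>7}  {round_percent(count, data['universe']):5.1f}%")
    print()

cross = classify_counts(
    datasets.cross_microgravity_crosstab()["cells"], classify_cross_microgravity
)
print(
    f"Only {cross['same_response']} of {datasets.TC_UNIVERSE_ANALYZED} TCs "
    "(< 0.1%) respond the same way to rocket microgravity and to fast "
    "clinorotation — the basis for concluding that clinostats do not "
    "reproduce the flight microgravity transcriptome response."
)
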