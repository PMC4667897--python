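"""Published diet-composition tables for the two snapper species.

These are the printed per-category diet summaries for red snapper (RS,
*Lutjanus campechanus*) and vermilion snapper (VS, *Rhomboplites
aurorubens*) from the northern Gulf of Mexico field study, restricted —
as printed — to the ten prey categories whose %IRI exceeded 1 for either
species.  They serve as ready-made utilization vectors for the overlap
index: Pianka's index is quadratic in the entries, so the omitted
low-importance categories perturb it only marginally.

``PUBLISHED_OVERLAP`` holds the study's reported Pianka indices and
null-model p-values for reference/comparison; nothing in the package
computes from them.
"""

from __future__ import annotations

import pandas as pd

PREY_CATEGORIES = (
    "Amphipod", "Copepod", "Crab", "Fish", "Gastropod",
    "Krill", "Mantis Shrimp", "Ostracod", "Shrimp", "Tunicate",
)

#: All-sites diet summary (means across stomachs; %O and %IRI pooled).
ALL_SITES = pd.DataFrame(
    {
        ("pctN", "RS"): [11.12, 5.86, 9.56, 27.61, 16.72, 0.28, 4.46, 1.83, 4.81, 3.74],
        ("pctN", "VS"): [25.56, 10.75, 11.99, 10.93, 4.35, 3.67, 6.90, 3.60, 6.78, 4.78],
        ("pctW", "RS"): [8.19, 0.17, 11.41, 36.19, 16.01, 0.31, 5.69, 0.81, 5.27, 3.31],
        ("pctW", "VS"): [22.12, 5.56, 12.78, 16.66, 3.12, 2.68, 12.00, 1.13, 7.14, 6.67],
        ("pctO", "RS"): [16.54, 9.77, 21.80, 42.11, 26.32, 0.75, 12.03, 4.51, 12.78, 8.27],
        ("pctO", "VS"): [48.91, 23.91, 28.26, 25.00, 14.13, 11.96, 23.91, 14.13, 18.48, 6.52],
        ("pctIRI", "RS"): [6.65, 1.23, 9.52, 55.96, 17.94, 0.01, 2.54, 0.25, 2.69, 1.21],
        ("pctIRI", "VS"): [47.26, 7.90, 7.53, 13.97, 2.14, 1.54, 9.16, 1.36, 5.21, 1.51],
    },
    index=PREY_CATEGORIES,
)

#: Single-species (allopatric) sites: %W and %IRI only, as printed.
ALLOPATRIC = pd.DataFrame(
    {
        ("pctW", "RS"): [8.57, 0.27, 8.37, 37.92, 13.47, 0.51, 6.26, 1.32, 6.70, 5.29],
        ("pctW", "VS"): [9.91, 5.10, 8.46, 22.37, 5.46, 7.81, 16.47, 0.25, 11.74, 6.28],
        ("pctIRI", "RS"): [6.93, 3.24, 5.46, 60.57, 13.86, 0.02, 2.82, 0.52, 2.70, 1.95],
        ("pctIRI", "VS"): [20.88, 9.47, 4.52, 23.14, 4.22, 9.36, 16.72, 1.12, 7.52, 0.54],
    },
    index=PREY_CATEGORIES,
)

#: Cohabited (sympatric) sites: %W and %IRI only, as printed.
SYMPATRIC = pd.DataFrame(
    {
        ("pctW", "RS"): [7.59, 0.00, 16.25, 33.45, 20.05, 0.00, 4.78, 0.00, 3.00, 0.15],
        ("pctW", "VS"): [28.33, 5.80, 14.98, 13.75, 1.93, 0.07, 9.72, 1.57, 4.81, 6.87],
        ("pctIRI", "RS"): [5.74, 0.00, 17.01, 45.81, 23.65, 0.00, 1.99, 0.01, 2.27, 0.36],
        ("pctIRI", "VS"): [59.31, 6.40, 8.47, 9.04, 1.15, 0.02, 5.42, 1.35, 3.58, 2.04],
    },
    index=PREY_CATEGORIES,
)

#: Reported Pianka indices (stratum -> metric -> (index, p)).
PUBLISHED_OVERLAP = {
    "all": {"pctIRI": (0.40469, 0.025), "pctN": (0.64887, 0.01), "pctW": (0.74122, 0.002)},
    "sympatric": {"pctIRI": (0.28163, 0.08), "pctN": (0.49207, 0.07), "pctW": (0.61908, 0.024)},
    "allopatric": {"pctIRI": (0.70298, 0.001), "pctN": (0.76185, 0.001), "pctW": (0.85092, 0.001)},
}


def utilization_vectors(table: pd.DataFrame, metric: str) -> tuple[list[float], list[float]]:
    """Return the (RS, VS) utilization vectors for ``metric`` from a table."""
    return list(table[(metric, "RS")]), list(table[(metric, "VS")])
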