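"""Published field-study reference values for *Cyrtodactylus nigriocularis*.

The stomach-flushing study of the black-eyed bent-toed gecko (Ba Den
Mountain, Tay Ninh Province, Vietnam; 51 individuals, 407 prey items)
published a per-category diet-composition table and per-group morphometric
summaries.  Those printed numbers are embedded here so that

* the composition arithmetic can be re-run from the published counts
  without the raw field data, and
* the synthetic generator defaults emulate the study's conditions.

Only published summary values appear here; the raw per-item measurements
were never printed and are not reproduced.
"""

from __future__ import annotations

import pandas as pd

#: Per-category (taxon_class, F, N, V) as printed: F = number of stomachs
#: containing the category, N = number of items, V = summed prey volume in
#: mm^3.  Category labels are verbatim, mixed taxonomic ranks included.
COMPOSITION_COUNTS: list[tuple[str, str, int, int, float]] = [
    ("Lumbricidae", "Annelida", 1, 3, 1493.33),
    ("Achatinidae", "Mollusca", 5, 23, 1869.09),
    ("Stylommatophora other", "Mollusca", 1, 1, 1.67),
    ("Araneae", "Arachnida", 20, 146, 990.90),
    ("Opiliones", "Arachnida", 13, 96, 841.44),
    ("Uropigi", "Arachnida", 1, 19, 1035.68),
    ("Scolopendridae", "Chilopoda", 6, 14, 1074.99),
    ("Armadillidiidae", "Malacostraca", 1, 2, 39.90),
    ("Blattidae", "Insecta", 5, 45, 815.22),
    ("Byrrhidae", "Insecta", 1, 1, 9.81),
    ("Elateroidea", "Insecta", 1, 1, 302.03),
    ("Culicidae", "Insecta", 1, 1, 14.65),
    ("Cicadellidae", "Insecta", 1, 1, 10.47),
    ("Pentatomidae", "Insecta", 2, 2, 159.15),
    ("Apidae", "Insecta", 1, 2, 198.87),
    ("Formicidae", "Insecta", 4, 9, 28.78),
    ("Termitidae", "Insecta", 3, 10, 63.52),
    ("Hepialidae", "Insecta", 1, 1, 133.97),
    ("Lepidoptera other", "Insecta", 1, 1, 70.52),
    ("Mantidae", "Insecta", 1, 6, 85.17),
    ("Acrididae", "Insecta", 4, 19, 247.76),
    ("Tetrigidae", "Insecta", 1, 4, 5.63),
]

#: Published percentages and IRI, for cross-checking the recomputation.
COMPOSITION_PRINTED: list[tuple[str, float, float, float, float]] = [
    # (category, %F, %N, %V, IRI)
    ("Lumbricidae", 1.33, 0.74, 15.73, 5.93),
    ("Achatinidae", 6.67, 5.65, 19.69, 10.67),
    ("Stylommatophora other", 1.33, 0.25, 0.02, 0.53),
    ("Araneae", 26.67, 35.87, 10.44, 24.33),
    ("Opiliones", 17.33, 23.59, 8.86, 16.59),
    ("Uropigi", 1.33, 4.67, 10.91, 5.64),
    ("Scolopendridae", 8.00, 3.44, 11.32, 7.59),
    ("Armadillidiidae", 1.33, 0.49, 0.42, 0.75),
    ("Blattidae", 6.67, 11.06, 8.59, 8.77),
    ("Byrrhidae", 1.33, 0.25, 0.10, 0.56),
    ("Elateroidea", 1.33, 0.25, 3.18, 1.59),
    ("Culicidae", 1.33, 0.25, 0.15, 0.58),
    ("Cicadellidae", 1.33, 0.25, 0.11, 0.56),
    ("Pentatomidae", 2.67, 0.49, 1.68, 1.61),
    ("Apidae", 1.33, 0.49, 2.09, 1.31),
    ("Formicidae", 5.33, 2.21, 0.30, 2.62),
    ("Termitidae", 4.00, 2.46, 0.67, 2.38),
    ("Hepialidae", 1.33, 0.25, 1.41, 1.00),
    ("Lepidoptera other", 1.33, 0.25, 0.74, 0.77),
    ("Mantidae", 1.33, 1.47, 0.90, 1.23),
    ("Acrididae", 5.33, 4.67, 2.61, 4.20),
    ("Tetrigidae", 1.33, 0.98, 0.06, 0.79),
]

#: Number of stomachs analysed (all yielded at least one item).
N_STOMACHS = 51

#: Group sizes as captured.
GROUP_SIZES = {"male": 15, "female": 33, "subadult": 3}

#: Per-group morphometrics: trait -> (mean, sd, min, max).  SVL and MW in
#: mm, BM in g.
MORPHOMETRICS = {
    "male": {
        "svl": (102.26, 10.39, 79.77, 112.31),
        "mw": (20.34, 2.35, 15.13, 23.65),
        "bm": (19.93, 5.68, 8.41, 26.89),
    },
    "female": {
        "svl": (102.76, 6.23, 83.20, 111.38),
        "mw": (19.71, 1.18, 16.61, 22.10),
        "bm": (20.51, 4.60, 10.28, 28.49),
    },
    "subadult": {
        "svl": (74.82, 2.40, 72.13, 76.74),
        "mw": (15.61, 1.91, 14.08, 17.75),
        "bm": (6.37, 1.20, 5.0, 7.20),
    },
}

#: Pearson correlations between morphometric traits (pooled adults).
MORPH_CORRELATIONS = {("svl", "mw"): 0.860, ("svl", "bm"): 0.948, ("mw", "bm"): 0.833}

#: Items per stomach: mean and SD (overdispersed: SD > mean), range 1-43.
PREY_COUNT_MEAN = 7.98
PREY_COUNT_SD = 8.42

#: Pooled prey dimensions, mm (n = 407).
PREY_LENGTH_MEAN = 7.53
PREY_LENGTH_SD = 6.55
PREY_WIDTH_MEAN = 1.44
PREY_WIDTH_SD = 1.10

#: COI alignment length used for the conspecificity check, and the maximum
#: uncorrected pairwise divergence reported across samples (percent).
COI_ALIGNMENT_LENGTH = 657
MAX_COI_DIVERGENCE_PCT = 0.46


def composition_counts_frame() -> pd.DataFrame:
    """Published per-category counts as a DataFrame (category, taxon_class, F, N, V)."""
    return pd.DataFrame(
        COMPOSITION_COUNTS, columns=["category", "taxon_class", "F", "N", "V"]
    )


def composition_printed_frame() -> pd.DataFrame:
    """Published percentage columns as a DataFrame (category, pctF, pctN, pctV, iri)."""
    return pd.DataFrame(
        COMPOSITION_PRINTED, columns=["category", "pctF", "pctN", "pctV", "iri"]
    )
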