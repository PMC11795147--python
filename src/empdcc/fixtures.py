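"""Reference tables for the tremolite habit/potency analysis.

These are the published per-mineral constants and per-dataset summary
statistics that parameterise the models and the synthetic-data generator:

* ``mineral_table`` — per mineral type: published Hodgson–Darnton R_M (%),
  biosolubility (years), mean width (µm) and mean surface area (µm²) of the
  main-window particle population, and the population-average DCC with the
  modelled R_M.
* ``dataset_table`` — the 24 tremolite / Libby-amphibole datasets (16
  testing, 3 validation, 5 initially unclassified): dimensional summary
  statistics, EMPA (stored as a fraction), criteria fraction, Pearson
  index, average DCC, a-priori and a-posteriori habit, and both modelled
  potencies.
* ``hc50_table`` — erythrocyte membranolysis HC50 per dataset (mg/ml and
  fibres x10^9/ml).
* ``rat_potency_table`` — intrapleural relative potency in rats with the
  matching dimensional inputs and modelled values.

All values are stored at their published precision and returned as copies;
treat them as read-only.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "mineral_table",
    "dataset_table",
    "hc50_table",
    "rat_potency_table",
    "testing_sets",
]

_MINERALS = [
    # mineral, rm_published, biosolubility_y, width_um, width_sd, sa_um2, sa_sd, avg_dcc, rm_modelled
    ("chrysotile", 0.0014, 0.3, 0.37, 0.0009, 21.50, 0.91, 0.085, 0.0013),
    ("amosite", 0.11, 74.0, 0.475, 0.0086, 14.48, 0.86, 0.030, 0.09),
    ("crocidolite", 0.52, 66.0, 0.31, 0.0004, 13.47, 0.45, 0.110, 1.18),
    ("anthophyllite", 0.056, 245.0, 0.83, 0.0162, 5.08, 1.57, 0.016, 0.083),
    ("libby_amphibole", 0.03, 49.0, 0.66, 0.009, 21.97, 0.91, 0.021, 0.025),
    ("erionite", 4.67, 181.0, 0.45, 0.012, 4.94, 1.16, 0.082, 2.1),
]

# group: testing | validation | unclassified.  habit_apriori: asbestiform |
# non_asbestiform | unclassified.  EMPA stored as a fraction of the main
# window; it enters the EMPA-linear potency model in percent.
_DATASETS = [
    # dataset, group, habit_apriori, habit_aposteriori, mineral,
    # mean_length, sd_length, mean_width, sd_width, mean_ar, sd_ar,
    # mean_ad, sd_ad, empa, sd_empa, mean_sa, sd_sa,
    # criteria_fraction, pearson_index, avg_dcc, rm_empa, rm_dcc
    ("Udaipur, India", "testing", "asbestiform", "asbestiform", "tremolite",
     9.30, 1.18, 0.77, 0.09, 30.53, 4.26, 3.67, 0.40, 0.027, 0.033, 18.15, 5.03,
     0.459, 0.29, 0.027, 0.018, 0.039),
    ("Lone Pine, CA", "testing", "asbestiform", "asbestiform", "tremolite",
     11.60, 0.25, 0.34, 0.02, 43.48, 0.89, 1.74, 0.08, 0.088, 0.007, 12.02, 1.05,
     0.945, 0.25, 0.048, 0.085, 0.144),
    ("Yamaga Mine, Japan", "testing", "asbestiform", "asbestiform", "tremolite",
     13.88, 0.50, 0.51, 0.04, 40.84, 1.79, 2.56, 0.17, 0.081, 0.014, 21.27, 2.12,
     0.818, 0.23, 0.040, 0.077, 0.097),
    ("Jamestown, CA", "testing", "asbestiform", "asbestiform", "tremolite",
     8.70, 0.49, 0.70, 0.04, 24.08, 1.76, 3.30, 0.16, 0.065, 0.013, 17.13, 2.08,
     0.574, 0.23, 0.025, 0.059, 0.034),
    ("Korea", "testing", "asbestiform", "asbestiform", "tremolite",
     11.40, 0.51, 0.35, 0.04, 48.31, 1.84, 1.77, 0.17, 0.147, 0.014, 11.93, 2.18,
     0.914, 0.13, 0.057, 0.150, 0.203),
    ("HSE sample (1)", "testing", "asbestiform", "asbestiform", "tremolite",
     9.74, 0.49, 0.30, 0.04, 46.31, 1.78, 1.54, 0.17, 0.269, 0.014, 9.25, 2.10,
     0.934, 0.21, 0.058, 0.284, 0.209),
    ("HSE Sample (2)", "testing", "asbestiform", "asbestiform", "tremolite",
     11.33, 0.50, 0.35, 0.04, 39.74, 1.80, 1.78, 0.17, 0.083, 0.014, 12.33, 2.13,
     0.937, 0.18, 0.044, 0.079, 0.116),
    ("Metsovo, Greece", "testing", "asbestiform", "asbestiform", "tremolite",
     8.65, 0.91, 0.32, 0.07, 52.84, 3.29, 1.56, 0.31, 0.306, 0.025, 7.62, 3.89,
     0.887, 0.28, 0.068, 0.325, 0.296),
    ("Miners Bay, Canada", "testing", "non_asbestiform", "non_asbestiform", "tremolite",
     8.42, 2.17, 0.84, 0.17, 10.59, 7.80, 4.08, 0.73, 0.000, 0.060, 28.09, 9.23,
     0.273, 0.54, 0.005, -0.012, 0.001),
    ("Gouverneur, NY", "testing", "non_asbestiform", "non_asbestiform", "tremolite",
     7.68, 1.15, 1.62, 0.09, 5.01, 4.14, 7.04, 0.39, 0.000, 0.032, 44.92, 4.90,
     0.000, 0.77, 0.001, -0.012, 0.000),
    ("Sparta, NJ", "testing", "non_asbestiform", "non_asbestiform", "tremolite",
     7.79, 0.51, 1.07, 0.04, 8.78, 1.83, 4.95, 0.17, 0.000, 0.014, 28.67, 2.16,
     0.150, 0.33, 0.004, -0.012, 0.001),
    ("Madagascar", "testing", "non_asbestiform", "non_asbestiform", "tremolite",
     8.06, 0.25, 1.31, 0.02, 7.06, 0.90, 5.83, 0.08, 0.000, 0.007, 36.80, 1.07,
     0.082, 0.67, 0.002, -0.012, 0.000),
    ("Shinness, Scotland", "testing", "non_asbestiform", "non_asbestiform", "tremolite",
     7.71, 0.36, 1.32, 0.03, 7.23, 1.31, 5.87, 0.12, 0.000, 0.010, 36.52, 1.55,
     0.103, 0.55, 0.003, -0.012, 0.000),
    ("Dornie", "testing", "non_asbestiform", "non_asbestiform", "tremolite",
     7.39, 0.53, 1.56, 0.04, 5.31, 1.89, 6.71, 0.18, 0.000, 0.015, 40.43, 2.24,
     0.037, 0.81, 0.002, -0.012, 0.000),
    ("Swansea", "testing", "non_asbestiform", "non_asbestiform", "tremolite",
     10.16, 0.50, 1.15, 0.04, 11.73, 1.79, 5.29, 0.17, 0.000, 0.014, 38.09, 2.11,
     0.229, 0.60, 0.005, -0.012, 0.001),
    ("NIOSH cleavage fragments", "testing", "non_asbestiform", "non_asbestiform", "tremolite",
     9.00, 0.47, 1.40, 0.04, 8.75, 1.70, 6.28, 0.16, 0.004, 0.013, 44.85, 2.01,
     0.150, 0.65, 0.005, -0.007, 0.001),
    ("Eastern New York", "validation", "asbestiform", "asbestiform", "tremolite",
     13.68, 0.75, 0.23, 0.06, 120.56, 2.71, 1.15, 0.25, 0.648, 0.021, 10.87, 3.21,
     0.945, 0.17, 0.138, 0.701, 1.362),
    ("Falls Village, CT", "validation", "non_asbestiform", "non_asbestiform", "tremolite",
     7.55, 1.69, 1.10, 0.13, 10.30, 6.10, 4.95, 0.57, 0.000, 0.047, 30.53, 7.22,
     0.278, 0.55, 0.007, -0.012, 0.002),
    ("Quebec, Canada", "validation", "non_asbestiform", "non_asbestiform", "tremolite",
     7.47, 2.27, 0.96, 0.18, 8.36, 8.19, 4.49, 0.76, 0.000, 0.063, 23.14, 9.68,
     0.100, 0.39, 0.003, -0.012, 0.000),
    ("El Dorado Hills, CA", "unclassified", "unclassified", "non_asbestiform", "tremolite",
     9.38, 0.19, 1.44, 0.01, 8.02, 0.67, 6.48, 0.06, 0.000, 0.005, 38.85, 0.79,
     0.114, 0.67, 0.003, -0.012, 0.000),
    ("Ala di Stura, Italy", "unclassified", "unclassified", "non_asbestiform", "tremolite",
     9.24, 0.52, 1.22, 0.04, 10.24, 1.87, 5.51, 0.17, 0.000, 0.014, 31.33, 2.21,
     0.198, 0.53, 0.005, -0.012, 0.001),
    ("Brazil", "unclassified", "unclassified", "non_asbestiform", "tremolite",
     7.45, 0.29, 1.31, 0.02, 7.31, 1.04, 5.77, 0.10, 0.000, 0.008, 33.81, 1.23,
     0.125, 0.35, 0.003, -0.012, 0.000),
    ("Barstow, CA", "unclassified", "unclassified", "asbestiform", "tremolite",
     11.64, 0.18, 0.69, 0.01, 32.26, 0.65, 3.28, 0.06, 0.080, 0.005, 25.08, 0.77,
     0.648, 0.35, 0.033, 0.075, 0.065),
    ("Libby, MT amphiboles", "unclassified", "unclassified", "asbestiform", "libby_amphibole",
     10.72, 0.30, 0.70, 0.01, 22.55, 1.28, 3.43, 0.04, 0.028, 0.004, 23.08, 0.86,
     0.626, 0.43, 0.021, 0.018, 0.019),
]

_HC50 = [
    # dataset, hc50_mg_ml, hc50_fibers_1e9_ml
    ("Udaipur, India", 2.81, 0.41),
    ("Jamestown, CA", 1.14, 0.17),
    ("Korea", 1.38, 0.51),
    ("Metsovo, Greece", 3.06, 1.7),
    ("Swansea", 2.53, 0.09),
    ("Libby, MT amphiboles", 2.07, 0.22),
]

_RAT = [
    # mineral, rat_potency_reported, avg_dcc, biosolubility_y, rm_modelled, rat_potency_modelled
    ("crocidolite", 1.22, 0.089, 66.0, 0.748, 1.20),
    ("amosite", 1.00, 0.041, 74.0, 0.161, 0.88),
    ("tremolite", 0.66, 0.032, 49.0, 0.059, 0.67),
    ("anthophyllite", 0.47, 0.0139, 245.0, 0.062, 0.68),
    ("nonfibrous_grunerite", 0.1, 0.0066, 74.0, 0.003, 0.06),
]

_mineral_df = pd.DataFrame(
    _MINERALS,
    columns=["mineral", "rm_published", "biosolubility_y", "width_um", "sd_width",
             "sa_um2", "sd_sa", "avg_dcc", "rm_modelled"],
)
_dataset_df = pd.DataFrame(
    _DATASETS,
    columns=["dataset", "group", "habit_apriori", "habit_aposteriori", "mineral",
             "mean_length", "sd_length", "mean_width", "sd_width", "mean_ar", "sd_ar",
             "mean_ad", "sd_ad", "empa", "sd_empa", "mean_sa", "sd_sa",
             "criteria_fraction", "pearson_index", "avg_dcc", "rm_empa", "rm_dcc"],
)
_hc50_df = pd.DataFrame(_HC50, columns=["dataset", "hc50_mg_ml", "hc50_fibers_1e9_ml"])
_rat_df = pd.DataFrame(
    _RAT,
    columns=["mineral", "rat_potency_reported", "avg_dcc", "biosolubility_y",
             "rm_modelled", "rat_potency_modelled"],
)


def mineral_table() -> pd.DataFrame:
    return _mineral_df.copy()


def dataset_table() -> pd.DataFrame:
    return _dataset_df.copy()


def testing_sets() -> pd.DataFrame:
    return _dataset_df[_dataset_df["group"] == "testing"].reset_index(drop=True).copy()


def hc50_table() -> pd.DataFrame:
    return _hc50_df.copy()


def rat_potency_table() -> pd.DataFrame:
    return _rat_df.copy()
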