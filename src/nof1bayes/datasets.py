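"""Built-in worked-example datasets.

Three small datasets accompany the methodology and are used throughout the
tests and the command-line ``fixture`` subcommand:

* ``table1`` — three hypothetical N = 1 persons with J = 4 conditions and
  R = 7 replications, evaluated under a full ordering and an
  averages-contrast hypothesis, together with the published complexity /
  fit / Bayes-factor values (rounded to 2 decimals as printed; the source
  table's column header was partly garbled and the complement columns were
  reconstructed from the surrounding prose).
* ``table3`` — seven hypothetical sets of per-person Bayes factors (P = 6,
  padded with fewer entries in Sets 1 and 2) illustrating P-BF, gP-BF,
  evidence rate and stability rate.
* ``table2`` — published per-person Bayes factors for a memory-and-reward
  within-subject experiment (26 participants, 8 conditions, R = 7) where
  four order hypotheses were compared against the unconstrained hypothesis
  and their complements.  Entries printed as "< 0.01" are censored upper
  bounds.  The published group-level summary (our ``table4``) is included:
  with censored inputs the recomputed geometric means are only upper
  bounds, so the published values also serve as direction references.
"""

from __future__ import annotations

from .hypotheses import ConditionLayout, HypothesisSet, parse_hypothesis
from .model import PersonCounts

__all__ = [
    "table1_layout",
    "table1_persons",
    "table1_hypotheses",
    "TABLE1_REFERENCE",
    "TABLE3_SETS",
    "TABLE3_REFERENCE",
    "TABLE2_COLUMNS",
    "TABLE2_CENSORED",
    "TABLE4_PUBLISHED",
    "zedelius_layout",
    "zedelius_hypotheses",
]


# --- table1 ----------------------------------------------------------------

def table1_layout() -> ConditionLayout:
    return ConditionLayout(names=("c1", "c2", "c3", "c4"), replications=7)


def table1_persons() -> list[PersonCounts]:
    layout = table1_layout()
    return [
        PersonCounts("1", (7, 5, 4, 1), layout),
        PersonCounts("2", (7, 2, 5, 1), layout),
        PersonCounts("3", (3, 4, 6, 1), layout),
    ]


def table1_hypotheses() -> HypothesisSet:
    layout = table1_layout()
    return HypothesisSet(
        [
            parse_hypothesis("c1 > c2 > c3 > c4", layout, label="H1"),
            parse_hypothesis("(c1 + c2)/2 > (c3 + c4)/2", layout, label="H2"),
        ],
        layout,
    )


#: published per-person values, rounded as printed
TABLE1_REFERENCE = {
    "1": {"c1": 0.04, "c2": 0.50, "f1": 0.56, "f2": 0.99,
          "BF1u": 13.16, "BF2u": 2.00, "BF1c": 28.39, "BF12": 6.59},
    "2": {"c1": 0.04, "c2": 0.50, "f1": 0.06, "f2": 0.89,
          "BF1u": 1.40, "BF2u": 1.79, "BF1c": 1.43, "BF12": 0.78, "BF2c": 8.09},
    "3": {"c1": 0.04, "c2": 0.50, "f1": 0.01, "f2": 0.51,
          "BF1u": 0.24, "BF2u": 1.01, "BF1c": 0.23, "BF12": 0.24, "BF2c": 1.04},
}


# --- table3 ----------------------------------------------------------------

TABLE3_SETS = {
    1: (9.00, 7.11),
    2: (3.20, 2.70, 2.30, 3.22),
    3: (1.40, 2.70, 1.80, 2.10, 1.60, 2.80),
    4: (0.80, 1.50, 2.50, 4.33, 3.10, 1.59),
    5: (0.90, 0.93, 0.85, 0.88, 6.30, 16.23),
    6: (6.40, 1.40, 1.80, 1.40, 1.60, 1.77),
    7: (1.01, 1.30, 2.50, 3.10, 2.60, 2.42),
}

#: published summary rows for the seven sets (2-decimal rounding)
TABLE3_REFERENCE = {
    "p_bf": {k: 64.00 for k in TABLE3_SETS},
    "gp_bf": {1: 8.00, 2: 2.83, 3: 2.00, 4: 2.00, 5: 2.00, 6: 2.00, 7: 2.00},
    "er": {1: 1.0, 2: 1.0, 3: 1.0, 4: 0.83, 5: 0.33, 6: 1.0, 7: 1.0},
    "sr": {1: 0.50, 2: 0.50, 3: 0.50, 4: 0.50, 5: 0.33, 6: 0.17, 7: 0.67},
}


# --- table2 / table4 -------------------------------------------------------

_LT = "lt"  # printed as "< value": true value below the stored bound

#: per-person Bayes factors, 26 participants; (value, censor-or-None)
TABLE2_COLUMNS = {
    "BF1u": [0.59, 3.33, 1.02, 0.03, 3.79, 543.90, 1.44, 0.01, 3.06, 2.60,
             0.05, 1.29, 0.30, 0.55, 21.84, 0.18, 22.30, 0.32, 0.01, 0.01,
             0.09, 15.78, 20.92, 0.15, 7.21, 0.06],
    "BF2u": [0.93, 1.49, 1.31, 0.10, 2.39, 17.95, 3.45, 0.16, 6.16, 3.41,
             0.24, 1.70, 3.50, 6.53, 2.01, 0.45, 5.15, 1.37, 0.01, 0.01,
             0.41, 5.59, 4.39, 1.16, 3.16, 0.13],
    "BF3u": [1.98, 4.67, 1.63, 0.58, 4.92, 13.74, 2.88, 0.02, 3.25, 2.75,
             0.55, 1.55, 2.66, 0.56, 6.41, 3.21, 3.88, 0.55, 0.03, 0.01,
             0.40, 4.82, 7.62, 0.32, 3.26, 0.38],
    "BF4u": [0.26, 0.45, 1.41, 1.22, 1.02, 1.43, 1.23, 0.19, 1.94, 0.99,
             1.21, 0.44, 0.79, 0.78, 1.73, 1.22, 1.91, 0.62, 1.96, 0.79,
             1.43, 1.58, 1.60, 1.01, 0.76, 0.58],
    "BF1c": [0.59, 3.33, 1.02, 0.03, 3.79, 551.21, 1.44, 0.01, 3.06, 2.60,
             0.05, 1.29, 0.30, 0.55, 21.85, 0.18, 22.31, 0.32, 0.01, 0.01,
             0.09, 15.78, 20.93, 0.15, 7.21, 0.06],
    "BF2c": [0.93, 1.52, 1.33, 0.10, 2.55, 68.72, 3.87, 0.15, 7.95, 3.81,
             0.23, 1.76, 3.93, 8.61, 2.10, 0.44, 6.28, 1.39, 0.01, 0.01,
             0.40, 6.98, 5.15, 1.17, 3.49, 0.13],
    "BF3c": [2.06, 5.54, 1.68, 0.57, 5.91, 30.30, 3.14, 0.02, 3.59, 2.97,
             0.54, 1.58, 2.86, 0.55, 8.35, 3.54, 4.42, 0.54, 0.03, 0.01,
             0.39, 5.77, 10.64, 0.31, 3.61, 0.37],
    "BF4c": [0.15, 0.29, 2.37, 1.55, 1.04, 2.51, 1.58, 0.10, 30.74, 0.97,
             1.53, 0.28, 0.65, 0.64, 6.28, 1.56, 20.64, 0.45, 40.41, 0.65,
             2.50, 3.68, 3.92, 1.02, 0.61, 0.41],
}

#: 0-based row indices of entries printed as "< 0.01"
TABLE2_CENSORED = {
    "BF1u": (7, 18, 19),
    "BF2u": (18, 19),
    "BF3u": (),
    "BF4u": (),
    "BF1c": (7, 18, 19),
    "BF2c": (18, 19),
    "BF3c": (),
    "BF4c": (),
}


def table2_censor_flags(column: str) -> tuple[str | None, ...]:
    idx = set(TABLE2_CENSORED[column])
    n = len(TABLE2_COLUMNS[column])
    return tuple(_LT if i in idx else None for i in range(n))


#: published group summary of the 26-person table (3-decimal rounding);
#: computed from the authors' unrounded Bayes factors, so with the rounded,
#: partly censored inputs above the geometric means reproduce only
#: approximately (and for BF1u/BF2u only as bounds).
TABLE4_PUBLISHED = {
    "gp_bf": {"BF1u": 0.510, "BF2u": 0.910, "BF3u": 1.125, "BF4u": 0.949,
              "BF1c": 0.511, "BF2c": 1.014, "BF3c": 1.235, "BF4c": 1.412},
    "er": {"BF1u": 0.500, "BF2u": 0.346, "BF3u": 0.615, "BF4u": 0.423,
           "BF1c": 0.500, "BF2c": 0.654, "BF3c": 0.615, "BF4c": 0.577},
    "sr": {"BF1u": 0.423, "BF2u": 0.308, "BF3u": 0.615, "BF4u": 0.385,
           "BF1c": 0.423, "BF2c": 0.654, "BF3c": 0.615, "BF4c": 0.500},
}


# --- memory-and-reward experiment layout -----------------------------------

def zedelius_layout() -> ConditionLayout:
    """The 8-condition within-subject layout of the memory-reward experiment.

    Factors: reward height (hr/lr), reward visibility (sup/sub), and
    interference (li/hi); 7 replications per condition.
    """
    return ConditionLayout(
        names=(
            "hr_sup_li", "hr_sup_hi", "hr_sub_li", "hr_sub_hi",
            "lr_sup_li", "lr_sup_hi", "lr_sub_li", "lr_sub_hi",
        ),
        replications=7,
    )


def zedelius_hypotheses() -> HypothesisSet:
    """The four competing order hypotheses of the memory-reward experiment.

    H1: full ordering of all eight conditions; H2 and H3: orderings of
    averages over one factor; H4: the reward-by-visibility interaction
    contrast.
    """
    layout = zedelius_layout()
    h1 = parse_hypothesis(
        "hr_sup_li > hr_sup_hi > hr_sub_li > hr_sub_hi > "
        "lr_sup_li > lr_sup_hi > lr_sub_li > lr_sub_hi",
        layout, label="H1",
    )
    h2 = parse_hypothesis(
        "(hr_sup_li + hr_sub_li)/2 > (hr_sup_hi + hr_sub_hi)/2 > "
        "(lr_sup_li + lr_sub_li)/2 > (lr_sup_hi + lr_sub_hi)/2",
        layout, label="H2",
    )
    h3 = parse_hypothesis(
        "(hr_sup_li + hr_sup_hi)/2 > (hr_sub_li + hr_sub_hi)/2 > "
        "(lr_sup_li + lr_sup_hi)/2 > (lr_sub_li + lr_sub_hi)/2",
        layout, label="H3",
    )
    h4 = parse_hypothesis(
        "(hr_sup_li + hr_sup_hi)/2 - (lr_sup_li + lr_sup_hi)/2 > "
        "(hr_sub_li + hr_sub_hi)/2 - (lr_sub_li + lr_sub_hi)/2",
        layout, label="H4",
    )
    return HypothesisSet([h1, h2, h3, h4], layout)
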