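"""Reference contingency tables of cohort characteristics by vaccination status.

Published patient counts (fully / partially / unvaccinated columns) from a
202-patient smartphone-monitoring oncology cohort, with the chi-squared
statistic printed alongside each panel. Used in worked examples and to
validate the Pearson chi-squared implementation: the printed statistics are
truncated (not rounded) to their displayed precision, and
:data:`REPRODUCIBLE_PANELS` lists the panels whose printed value the plain
Pearson statistic reproduces from the printed counts. The age, cancer-type
and cisplatin panels do not reproduce from their printed counts (they were
evidently computed on differently binned raw data) and are kept here only
for completeness.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["CharacteristicPanel", "PANELS", "REPRODUCIBLE_PANELS"]

VACCINATION_COLUMNS = ("fully", "partially", "unvaccinated")


@dataclass(frozen=True)
class CharacteristicPanel:
    name: str
    row_labels: tuple[str, ...]
    counts: tuple[tuple[int, int, int], ...]
    printed_chi2: str  # as printed, truncated to displayed precision


PANELS: dict[str, CharacteristicPanel] = {
    p.name: p
    for p in [
        CharacteristicPanel(
            "age",
            ("18-25", "26-40", "41-64", ">=65"),
            ((5, 1, 1), (13, 5, 7), (78, 15, 18), (47, 5, 7)),
            "6.884",
        ),
        CharacteristicPanel(
            "sex", ("male", "female"), ((57, 15, 12), (86, 11, 21)), "3.322"
        ),
        CharacteristicPanel(
            "education",
            ("academic degree", "no academic degree"),
            ((89, 15, 19), (54, 11, 14)),
            "0.372",
        ),
        CharacteristicPanel(
            "marital_status",
            ("single", "married", "divorced", "widowed"),
            ((13, 4, 3), (103, 17, 21), (15, 2, 7), (12, 3, 2)),
            "4.814",
        ),
        CharacteristicPanel(
            "living_area",
            ("urban", "rural"),
            ((106, 17, 24), (37, 9, 9)),
            "0.848",
        ),
        CharacteristicPanel(
            "occupation",
            ("employed", "unemployed", "retired", "other"),
            ((83, 13, 19), (9, 3, 5), (40, 6, 8), (11, 4, 1)),
            "6.221",
        ),
        CharacteristicPanel(
            "smartphone_os",
            ("android", "ios", "other"),
            ((120, 24, 28), (23, 1, 5), (0, 1, 0)),
            "9.263",
        ),
        CharacteristicPanel(
            "history_of_covid19",
            ("yes", "no"),
            ((53, 12, 20), (90, 14, 13)),
            "6.3",
        ),
        CharacteristicPanel(
            "history_of_cancer_surgery",
            ("yes", "no"),
            ((65, 11, 10), (78, 15, 23)),
            "2.518",
        ),
        CharacteristicPanel(
            "history_of_biological_therapy",
            ("yes", "no"),
            ((13, 3, 1), (130, 23, 32)),
            "1.655",
        ),
        CharacteristicPanel(
            "history_of_chemotherapy",
            ("yes", "no"),
            ((55, 7, 7), (88, 19, 26)),
            "4.241",
        ),
        CharacteristicPanel(
            "current_chemotherapy",
            ("yes", "no"),
            ((74, 11, 17), (69, 15, 16)),
            "0.8",
        ),
        CharacteristicPanel(
            "currently_on_cisplatin",
            ("yes", "no"),
            ((19, 4, 11), (124, 22, 22)),
            "5.944",
        ),
    ]
}

#: panels whose printed chi-squared the plain Pearson statistic reproduces
#: from the printed counts (after truncation to the printed precision)
REPRODUCIBLE_PANELS: tuple[str, ...] = (
    "history_of_covid19",
    "sex",
    "marital_status",
    "occupation",
    "history_of_cancer_surgery",
    "history_of_chemotherapy",
    "history_of_biological_therapy",
    "smartphone_os",
    "current_chemotherapy",
)
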