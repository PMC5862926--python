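"""Two classic public teaching datasets used by the worked examples.

* ``load_hair_color`` -- the 1970s Melbourne pain-threshold experiment:
  19 participants in four hair-colour groups.  The values are the published
  textbook data (a classical one-way ANOVA on them gives p = .004).
* ``load_singers`` -- heights (inches) of the 235 members of the New York
  Choral Society (1979), with voice part recoded within gender to a
  four-level pitch factor (very low .. very high), giving a 2 x 4
  between-subjects layout.
"""

from __future__ import annotations

from importlib import resources

from ..data import DataTable, read_csv

__all__ = ["load_hair_color", "load_singers"]

_PAIN_THRESHOLD = {
    "LightBlond": [62, 60, 71, 55, 48],
    "DarkBlond": [63, 57, 52, 41, 43],
    "LightBrunette": [42, 50, 41, 37],
    "DarkBrunette": [32, 39, 51, 30, 35],
}


def load_hair_color() -> DataTable:
    """Pain tolerance scores by hair colour (19 observations, 4 groups)."""
    scores: list[float] = []
    colours: list[str] = []
    for colour, values in _PAIN_THRESHOLD.items():
        scores.extend(float(v) for v in values)
        colours.extend([colour] * len(values))
    return DataTable({"Pain Tolerance": scores, "Hair Color": colours},
                     {"Pain Tolerance": "continuous", "Hair Color": "nominal"})


def load_singers() -> DataTable:
    """Singer heights with Gender (2) and Pitch (4) factors, n = 235."""
    with resources.as_file(resources.files(__package__) / "singers.csv") as path:
        table = read_csv(path)
    table.set_level("Height", "continuous")
    return table
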