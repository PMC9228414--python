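"""Accessors for the small data tables shipped with the package.

* ``fedbatch_rate_panels.tsv`` — measured specific-rate panels of the four
  fed-batch modes (CK and three n-propanol feed rates) over the rapid
  erythromycin synthesis window (96-108 h).
* ``model_census.tsv`` — the published census of the iJL1426
  reconstruction (gene/reaction/metabolite counts and annotation totals).
* ``carbon_sources_observed.tsv`` / ``nitrogen_sources_observed.tsv`` —
  experimentally observed growth/no-growth phenotype panels (27 carbon and
  31 nitrogen sources) used to score screen accuracy.
"""

from __future__ import annotations

import csv
from importlib import resources
from pathlib import Path
from typing import Dict, List, Tuple

from .recovery import RatePanel, load_rate_panels
from .screens import load_observations


def data_path(name: str) -> Path:
    with resources.as_file(resources.files("erygem") / "data" / name) as p:
        return Path(p)


def fedbatch_rate_panels() -> Dict[str, RatePanel]:
    """The four measured rate panels (modes CK, mode1, mode2, mode3)."""
    return load_rate_panels(data_path("fedbatch_rate_panels.tsv"))


def model_census() -> Dict[str, int]:
    """Published census statistics of the iJL1426 reconstruction."""
    out = {}
    with open(data_path("model_census.tsv")) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out[row["statistic"]] = int(row["value"])
    return out


def annotation_coverage_percent(census: Dict[str, int] | None = None) -> float:
    """Annotated share of the genome, percent to one decimal."""
    census = census or model_census()
    return round(100.0 * census["genes_assigned"] / census["total_genes"], 1)


def carbon_source_observations() -> List[Tuple[str, str, str]]:
    return load_observations(data_path("carbon_sources_observed.tsv"))


def nitrogen_source_observations() -> List[Tuple[str, str, str]]:
    return load_observations(data_path("nitrogen_sources_observed.tsv"))
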