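import datetime as dt

import pytest

from trophicoverlap.schemas import PreyItem, StomachSample

STOMACH_HEADER = ("fish_id,species,fork_length_mm,site_id,date,reef_type,"
                  "depth_m,prey_taxon,count,weight_g,is_bait,is_unidentifiable")


@pytest.fixture
def write_csv(tmp_path):
    """Write lines to a temp CSV and return its path."""

    def _write(lines, name="table.csv"):
        p = tmp_path / name
        p.write_text("\n".join(lines) + "\n")
        return p

    return _write


def make_stomach(fish_id="F1", species="RS", items=(), site="S1",
                 reef="artificial", depth=35.0, season=None, cohabitation=None):
    date = dt.date(2011, 4, 20) if season in (None, "spring") else dt.date(2011, 8, 20)
    return StomachSample(
        fish_id=fish_id, species=species, fork_length=400.0, site_id=site,
        date=date, season=season or "spring", reef_type=reef, depth=depth,
        items=tuple(items), cohabitation=cohabitation,
    )


def item(taxon, count=1, weight=0.1, bait=False, unid=False):
    return PreyItem(taxon=taxon, count=count, weight=weight,
                    is_bait=bait, is_unidentifiable=unid)
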