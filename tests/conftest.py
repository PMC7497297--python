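import pytest
from hypothesis import HealthCheck, settings

import mzannotate as mz
from mzannotate.search import SearchHit

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def demo_db(tmp_path_factory):
    """Extended database over the curated demo metabolite table."""
    path = tmp_path_factory.mktemp("demo") / "demo.db"
    db, report = mz.build_extended(mz.demo_compounds(), store_path=path)
    assert not report.skipped
    return db


@pytest.fixture(scope="session")
def synthetic_500(tmp_path_factory):
    """(compounds, db, report) for a 500-compound synthetic build."""
    compounds = mz.gen_compound_db(500, seed=1)
    path = tmp_path_factory.mktemp("syn") / "synthetic500.db"
    db, report = mz.build_extended(compounds, store_path=path)
    return compounds, db, report


_SCAN_CACHE = {}


def linear_scan(db, query):
    """Brute-force search oracle: fetch every row, filter and sort in Python."""
    rows = _SCAN_CACHE.get(db.path)
    if rows is None:
        with db.connect() as con:
            rows = con.execute(
                "SELECT v.source, v.compound_id, c.name, c.formula, v.adduct,"
                " v.isotope, v.polarity, v.mz FROM variants v JOIN compounds c"
                " ON c.source = v.source AND c.id = v.compound_id"
            ).fetchall()
        _SCAN_CACHE[db.path] = rows
    lo = query.mz * (1 - query.ppm * 1e-6)
    hi = query.mz * (1 + query.ppm * 1e-6)
    hits = []
    for source, cid, name, formula, adduct, isotope, pol, mzv in rows:
        if not lo <= mzv <= hi:
            continue
        if query.polarity != "both" and pol != query.polarity:
            continue
        if query.sources is not None and source not in query.sources:
            continue
        if query.main_peak_only and isotope != "M0":
            continue
        err = 1e6 * (query.mz - mzv) / mzv
        hits.append(
            SearchHit(query.mz, source, cid, name, formula, adduct, isotope,
                      mzv, err)
        )
    hits.sort(key=lambda h: (abs(h.ppm_error), h.source, h.compound_id, h.adduct))
    return hits
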