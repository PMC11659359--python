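"""Study orchestration: determinism, grid structure, comparison logic."""

import numpy as np
import pytest

import emtsens as es


@pytest.fixture(scope="module")
def small_study():
    cfg = es.StudyConfig(N=150, seed=3, frames=("dimensional", "set3", "set7"))
    return es.run_study(cfg)


def test_study_structure(small_study):
    assert set(small_study.frames) == {"dimensional", "set3", "set7"}
    dim = small_study.frames["dimensional"]
    assert dim.table.shape == (11, 16)  # 11 parameters x (8 groups x 2 outputs)
    assert small_study.frames["set3"].table.shape == (6, 16)
    assert (small_study.frames["set3"].table.abs() <= 1).all().all()
    # set 3 never samples its gamma grouping B1
    assert "B1" not in small_study.frames["set3"].table.index


def test_study_is_deterministic(small_study, tmp_path):
    again = es.run_study(es.StudyConfig(N=150, seed=3,
                                        frames=("dimensional", "set3", "set7")))
    for name, fr in small_study.frames.items():
        assert fr.table.equals(again.frames[name].table)
    a, b = tmp_path / "a", tmp_path / "b"
    small_study.write(a)
    again.write(b)
    for f in sorted(p.name for p in a.iterdir()):
        assert (a / f).read_bytes() == (b / f).read_bytes(), f


def test_shared_design_reuses_unit_draws(small_study):
    """The same (seed, column-name) stream feeds every frame, so the shared
    columns of set3 and set7 sit at identical unit-interval positions."""
    m3, m7 = small_study.frames["set3"].matrix, small_study.frames["set7"].matrix
    shared = [n for n in m3.names if n in m7.names]
    for n in shared:
        r3 = next(r for r in m3.ranges if r.name == n)
        r7 = next(r for r in m7.ranges if r.name == n)
        u3 = (m3.column(n) - r3.lo) / (r3.hi - r3.lo)
        u7 = (m7.column(n) - r7.lo) / (r7.hi - r7.lo)
        assert u3 == pytest.approx(u7, abs=1e-12)


def test_independent_designs_differ():
    cfg = es.StudyConfig(N=40, seed=3, frames=("set3", "set7"), shared_design=False)
    res = es.run_study(cfg)
    m3, m7 = res.frames["set3"].matrix, res.frames["set7"].matrix
    r3 = next(r for r in m3.ranges if r.name == "A2")
    r7 = next(r for r in m7.ranges if r.name == "A2")
    u3 = (m3.column("A2") - r3.lo) / (r3.hi - r3.lo)
    u7 = (m7.column("A2") - r7.lo) / (r7.hi - r7.lo)
    assert not np.allclose(u3, u7)


def test_slug_prcc_signs(small_study):
    """Production raises and degradation lowers Slug in every condition."""
    dim = small_study.frames["dimensional"]
    for (group, output), res in dim.prcc.items():
        if output != "S":
            continue
        assert res.rho["alpha2"] > 0, group
        assert res.rho["beta2"] < 0, group


def test_slug_dependence_at_isolated_cell(small_study):
    """An isolated, untreated cell's Slug level is set by its own production
    and degradation rates only."""
    dim = small_study.frames["dimensional"]
    res = dim.prcc[("C=0,T=0", "S")]
    assert es.classify_significance(res) == {"alpha2", "beta2"}


def test_grouping_symbols_derived_symbolically():
    g1 = es.grouping_symbols(1)
    assert g1["K0"] == frozenset({"k0", "alpha1"})
    assert g1["A1"] == frozenset()  # the gamma grouping cancels to 1
    g7 = es.grouping_symbols(7)
    assert g7["A2"] == frozenset({"alpha2", "beta2", "IC_S"})
    union = set()
    for k in range(1, 8):
        for syms in es.grouping_symbols(k).values():
            union |= set(syms)
    # the input rescaling constants appear in no grouping of any set
    assert "IC_C" not in union and "IC_T" not in union
    assert union == set(es.model.DIMENSIONAL_NAMES) - {"IC_C", "IC_T"}


def test_report_discrepancies_logic():
    dim_grid = {
        ("C=1,T=0", "E"): {"IC_C"},
        ("C=1,T=0", "S"): {"alpha2", "beta2"},
    }
    agree = {("mu=0.46,theta=0", "e"): {"B1"}, ("mu=0.46,theta=0", "s"): {"A2", "B2"}}
    disagree = {("mu=0.46,theta=0", "e"): {"K0", "A2"},
                ("mu=0.46,theta=0", "s"): {"A2", "B2"}}
    rep = es.report_discrepancies({"dimensional": dim_grid, "set1": agree, "set3": disagree})
    # outputs are reported in frame-neutral (upper-case) notation
    assert [(g, o) for g, o, _ in rep.discrepancies] == [("mu=0.46,theta=0", "E")]
    # IC_C is significant dimensionally but belongs to no grouping of any set
    assert ("IC_C", "C=1,T=0", "E") in rep.lost_parameters
    same = es.report_discrepancies({"set1": agree, "set3": agree})
    assert same.discrepancies == ()
    short = {("mu=0.46,theta=0", "e"): {"B1"}}
    with pytest.raises(ValueError, match="grid cells"):
        es.report_discrepancies({"set1": agree, "set3": short})


def test_single_frame_study_has_no_report():
    res = es.run_study(es.StudyConfig(N=30, seed=1, frames=("dimensional",)))
    assert res.report is None
    assert res.frames["dimensional"].table.shape == (11, 16)


def test_config_validation():
    with pytest.raises(ValueError, match="unknown frames"):
        es.StudyConfig(frames=("dimensional", "set9"))
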