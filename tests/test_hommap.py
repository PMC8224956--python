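import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from frostmap.hommap import (CONCORDANT, DISCORDANT, UNINFORMATIVE,
                             ConcordanceRule, classify_concordance, pool_af,
                             rank_candidates, window_scan)


def _row(founder=(15, 15), het=(15, 15), hom=(1, 29), wt=(29, 1),
         scaffold="s1", pos=100):
    return {"scaffold": scaffold, "pos": pos, "ref": "A", "alt": "T",
            "founder_ref": founder[0], "founder_alt": founder[1],
            "het_ref": het[0], "het_alt": het[1],
            "hom_ref": hom[0], "hom_alt": hom[1],
            "wt_ref": wt[0], "wt_alt": wt[1]}


def test_pool_af_basic_and_degenerate():
    assert pool_af(15, 15) == 0.5
    assert pool_af(0, 30) == 1.0
    assert np.isnan(pool_af(0, 0))
    with pytest.raises(ValueError):
        pool_af(-1, 5)


def test_expected_pattern_is_concordant():
    df = pd.DataFrame([_row(founder=(15, 15), het=(15, 15), hom=(2, 38), wt=(38, 2))])
    assert classify_concordance(df)[0] == CONCORDANT


def test_hom_pool_bound_is_strict():
    # hom AF exactly 0.85 -> discordant under the strict > bound
    df = pd.DataFrame([_row(hom=(6, 34))])  # 34/40 = 0.85
    assert classify_concordance(df)[0] == DISCORDANT
    df = pd.DataFrame([_row(hom=(5, 35))])  # 0.875 > 0.85
    assert classify_concordance(df)[0] == CONCORDANT


def test_wt_pool_bound_is_strict():
    df = pd.DataFrame([_row(wt=(34, 6))])  # 0.15 exactly -> fails < 0.15
    assert classify_concordance(df)[0] == DISCORDANT


def test_het_range_inclusive_at_both_ends():
    for het in ((18, 12), (12, 18)):  # AF 0.4 and 0.6
        df = pd.DataFrame([_row(het=het)])
        assert classify_concordance(df)[0] == CONCORDANT


def test_low_depth_pool_is_uninformative():
    df = pd.DataFrame([_row(wt=(9, 1))])  # wt depth 10 < 30
    assert classify_concordance(df)[0] == UNINFORMATIVE
    df = pd.DataFrame([_row(hom=(0, 0))])  # missing AF
    assert classify_concordance(df)[0] == UNINFORMATIVE


# ---------------------------------------------------------------------------
# window scan
# ---------------------------------------------------------------------------

def _random_pool_table(rng, n=1000, n_scaffolds=6, span=60_000):
    rows = []
    for i in range(n):
        scaf = f"s{rng.integers(1, n_scaffolds + 1)}"
        depths = rng.integers(0, 70, size=8)
        rows.append({"scaffold": scaf, "pos": int(rng.integers(1, span)),
                     "ref": "A", "alt": "T",
                     "founder_ref": int(depths[0]), "founder_alt": int(depths[1]),
                     "het_ref": int(depths[2]), "het_alt": int(depths[3]),
                     "hom_ref": int(depths[4]), "hom_alt": int(depths[5]),
                     "wt_ref": int(depths[6]), "wt_alt": int(depths[7])})
    df = pd.DataFrame(rows).sort_values(["scaffold", "pos"], kind="mergesort")
    return df.reset_index(drop=True)


def _brute_force_windows(df, rule, window_size, min_variants):
    """Independent per-variant re-evaluation of the windowed statistic."""
    def af(r, p):
        tot = r[f"{p}_ref"] + r[f"{p}_alt"]
        return (r[f"{p}_alt"] / tot) if tot > 0 else None

    out = {}
    for _, r in df.iterrows():
        k = (r["scaffold"], (r["pos"] - 1) // window_size)
        out.setdefault(k, [0, 0])
        informative = all(
            (r[f"{p}_ref"] + r[f"{p}_alt"]) >= rule.min_depth and af(r, p) is not None
            for p in ("founder", "het", "hom", "wt"))
        if not informative:
            continue
        out[k][0] += 1
        conc = (rule.het_lo <= af(r, "het") <= rule.het_hi
                and rule.founder_lo <= af(r, "founder") <= rule.founder_hi
                and af(r, "hom") > rule.hom_min
                and af(r, "wt") < rule.wt_max)
        if conc:
            out[k][1] += 1
    return out


def test_window_scan_equals_brute_force_on_random_fixture(rng):
    df = _random_pool_table(rng, n=1000)
    rule = ConcordanceRule()
    windows = window_scan(df, rule, 10_000, 5)
    oracle = _brute_force_windows(df, rule, 10_000, 5)
    for _, w in windows.iterrows():
        ninf, ncon = oracle.get((w["scaffold"], w["start"] // 10_000), (0, 0))
        assert w["n_informative"] == ninf
        assert w["n_concordant"] == ncon
        if ninf:
            assert w["fraction"] == pytest.approx(ncon / ninf)
        assert w["qualifying"] == (ninf >= 5)


def test_printed_fraction_for_twenty_of_twentytwo():
    """A window holding 22 informative variants, 20 concordant, reports
    fraction 20/22 ~ 0.909."""
    rows = [_row(pos=200 + 10 * i) for i in range(20)]
    rows += [_row(pos=5000, hom=(20, 20)), _row(pos=5100, wt=(20, 20))]
    df = pd.DataFrame(rows)
    w = window_scan(df, ConcordanceRule(), 10_000, 5)
    assert len(w) == 1
    assert w["n_informative"].iat[0] == 22 and w["n_concordant"].iat[0] == 20
    assert w["fraction"].iat[0] == pytest.approx(20 / 22)
    assert w["fraction"].iat[0] == pytest.approx(0.909, abs=5e-4)


def test_windows_with_fewer_than_five_variants_do_not_qualify():
    df = pd.DataFrame([_row(pos=100 + i * 7) for i in range(4)])
    w = window_scan(df, ConcordanceRule(), 10_000, 5)
    assert w["n_informative"].iat[0] == 4
    assert not w["qualifying"].iat[0]


def test_empty_table_gives_empty_output():
    df = pd.DataFrame(columns=["scaffold", "pos", "ref", "alt"] +
                      [f"{p}_{s}" for p in ("founder", "het", "hom", "wt")
                       for s in ("ref", "alt")])
    assert len(window_scan(df, ConcordanceRule())) == 0


def test_unsorted_input_rejected(rng):
    df = _random_pool_table(rng, n=50).iloc[::-1].reset_index(drop=True)
    with pytest.raises(ValueError, match="sorted"):
        window_scan(df, ConcordanceRule())


def test_windows_tile_from_zero_with_given_lengths(rng):
    df = pd.DataFrame([_row(pos=25_000)])
    w = window_scan(df, ConcordanceRule(), 10_000, 5, {"s1": 40_000})
    assert w["start"].tolist() == [0, 10_000, 20_000, 30_000]
    assert w["end"].tolist() == [10_000, 20_000, 30_000, 40_000]


@settings(deadline=None, derandomize=True, max_examples=20)
@given(seed=st.integers(0, 1000))
def test_fractions_invariant_to_streaming_order(seed):
    rng = np.random.default_rng(seed)
    df = _random_pool_table(rng, n=120, n_scaffolds=3, span=30_000)
    shuffled = df.sample(frac=1, random_state=seed).sort_values(
        ["scaffold", "pos"], kind="mergesort").reset_index(drop=True)
    a = window_scan(df, ConcordanceRule())
    b = window_scan(shuffled, ConcordanceRule())
    pd.testing.assert_frame_equal(a, b)


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

def _win(scaffold, start, ninf, ncon, qualifying=True):
    return {"scaffold": scaffold, "start": start, "end": start + 10_000,
            "n_informative": ninf, "n_concordant": ncon,
            "fraction": ncon / ninf if ninf else np.nan,
            "qualifying": qualifying}


def test_rank_ties_break_by_informative_count_then_name_then_start():
    wins = pd.DataFrame([
        _win("s2", 0, 5, 5),       # fraction 1.0
        _win("s1", 0, 22, 20),     # 0.909..., 22 informative
        _win("s3", 0, 6, 5),       # 0.833
    ])
    ranked, _ = rank_candidates(wins, top_k=3)
    assert ranked["scaffold"].tolist() == ["s2", "s1", "s3"]
    # equal fractions: more informative variants first
    wins = pd.DataFrame([_win("s1", 0, 10, 9), _win("s2", 0, 20, 18),
                         _win("s0", 10_000, 20, 18)])
    ranked, _ = rank_candidates(wins, top_k=3)
    assert ranked[["scaffold", "start"]].values.tolist() == [
        ["s0", 10_000], ["s2", 0], ["s1", 0]]


def test_rank_excludes_non_qualifying_and_reports_distribution():
    wins = pd.DataFrame([_win("s1", 0, 10, 0), _win("s2", 0, 3, 3, False)])
    ranked, (counts, edges) = rank_candidates(wins, top_k=5)
    assert len(ranked) == 1 and ranked["scaffold"].iat[0] == "s1"
    assert counts.sum() == 1  # distribution over qualifying windows only
    with pytest.raises(ValueError):
        rank_candidates(wins, top_k=0)
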