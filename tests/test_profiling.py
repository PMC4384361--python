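"""Pattern-site discovery and aggregated pause profiles."""

import numpy as np
import pytest
from scipy import stats

import pausewave as pw
from pausewave.exceptions import PatternError, ValidationError

G4_PATTERN = "(GGG(.){1,7}GGG(.){1,7}GGG(.){1,7}GGG)"


def make_read(read_id, start, bases, strand="+", ipd=None):
    n = len(bases)
    return pw.KineticRead(
        read_id=read_id,
        reference_name="r",
        reference_start=start,
        strand=strand,
        bases=bases,
        ipd_seconds=np.full(n, 0.2) if ipd is None else np.asarray(ipd, float),
        insert_count=np.zeros(n, dtype=int),
    )


class TestFindSites:
    def test_g_quadruplex_toy_sequence(self):
        ref = pw.Reference("r", "AAGGGTGGGTGGGTGGGAA")
        sites = [s for s in pw.find_sites(ref, G4_PATTERN) if s.strand == "+"]
        assert len(sites) == 1
        assert (sites[0].start, sites[0].end) == (2, 17)
        assert sites[0].matched == "GGGTGGGTGGGTGGG"

    def test_palindromic_pattern_pairs_strands(self):
        ref = pw.Reference("r", "AATTCGCGCGCGCGATAT")
        sites = pw.find_sites(ref, "CGCGCGCGCG")
        assert len(sites) == 2
        assert {s.strand for s in sites} == {"+", "-"}
        assert all((s.start, s.end) == (4, 14) for s in sites)
        # the reverse-strand matched sequence equals the revcomp slice
        assert all(s.matched == "CGCGCGCGCG" for s in sites)

    def test_reverse_strand_coordinates(self):
        ref = pw.Reference("r", "AAAGGCGGCTTT")  # revcomp contains GCCGCC
        sites = pw.find_sites(ref, "GCCGCC")
        assert len(sites) == 1
        s = sites[0]
        assert (s.start, s.end, s.strand) == (3, 9, "-")
        assert s.matched == "GCCGCC"

    def test_no_match_and_forward_only(self):
        ref = pw.Reference("r", "ATATATAT")
        assert pw.find_sites(ref, "GGGG") == []
        ref2 = pw.Reference("r", "AAAGGCGGCTTT")
        assert pw.find_sites(ref2, "GCCGCC", both_strands=False) == []

    def test_invalid_pattern_raises(self):
        with pytest.raises(PatternError):
            pw.find_sites(pw.Reference("r", "ACGT"), "GGG(")

    def test_overlapped_scan(self):
        ref = pw.Reference("r", "AGGGGGA")
        nonov = [s for s in pw.find_sites(ref, "GGG", both_strands=False)]
        ov = [s for s in pw.find_sites(ref, "GGG", both_strands=False, overlapped=True)]
        assert len(nonov) == 1
        assert len(ov) == 3


class TestExtractProfiles:
    def test_constant_ipd_mean_quantiles_and_smooth_scaling(self):
        """Constant IPD 0.2: mean = q90 = q95 = 0.2 everywhere covered;
        smooth-2 = 0.2*sqrt(2), smooth-4 = 0.2*2 with full context."""
        ref = pw.Reference("r", "A" * 20 + "GGCGGCGGCGG" + "A" * 20)
        sites = [s for s in pw.find_sites(ref, "GGCGGCGGCGG") if s.strand == "+"]
        reads = [make_read("r1", 0, ref.sequence)]
        prof = pw.extract_profiles(sites, reads, window=32)
        raw = prof.data[prof.data.track == "raw"]
        covered = raw[raw["count"] > 0]
        assert len(covered) == 32
        np.testing.assert_allclose(covered["mean"], 0.2)
        np.testing.assert_allclose(covered["q90"], 0.2)
        np.testing.assert_allclose(covered["q95"], 0.2)
        sm2 = prof.data[(prof.data.track == "smooth2") & (prof.data["count"] > 0)]
        np.testing.assert_allclose(sm2["mean"], 0.2 * np.sqrt(2))
        sm4 = prof.data[(prof.data.track == "smooth4") & (prof.data["count"] > 0)]
        np.testing.assert_allclose(sm4["mean"], 0.2 * 2)

    def test_quantiles_against_order_statistics_oracle(self):
        """20 observations at one position; q90/q95 follow the linear
        interpolation rule h = (n-1)p + 1 on the sorted values."""
        vals = [0.1 * k for k in range(1, 19)] + [4.0, 8.0]
        ref = pw.Reference("r", "AAAACCCCGGGGTTTT")
        sites = [pw.PatternSite("r", 8, 9, "+", "G")]
        reads = [
            make_read(f"r{i}", 0, ref.sequence, ipd=np.full(16, v))
            for i, v in enumerate(vals)
        ]
        prof = pw.extract_profiles(sites, reads, window=16, anchor=8)
        raw = prof.data[(prof.data.track == "raw") & (prof.data.position == 8)].iloc[0]
        s = np.sort(vals)
        # h = (n-1)p + 1 = 18.1 for p=0.9, n=20 -> s[17] + 0.1*(s[18]-s[17])
        assert raw["q90"] == pytest.approx(s[17] + 0.1 * (s[18] - s[17]))
        assert raw["q95"] == pytest.approx(s[18] + 0.05 * (s[19] - s[18]))
        assert raw["count"] == 20

    def test_pause_recovery(self, pause_dataset):
        """q90 of raw IPD peaks exactly at the injected pause offset and is
        clearly elevated over the background (p=0.1, tau=4 s, 500 reads).

        With an additive Exp(tau) pause at probability exactly 0.1, the
        population 90th percentile sits near the lower edge of the pause
        component, so the elevation is moderate (about 2-3x background),
        but localization by argmax is sharp."""
        cfg, motif, reference, reads, truth = pause_dataset
        sites = pw.find_sites(reference, motif)
        prof = pw.extract_profiles(sites, reads)
        raw = prof.data[prof.data.track == "raw"].set_index("position")
        pause_pos = prof.anchor + 2
        in_pattern = range(prof.anchor, prof.anchor + len(motif))
        background = raw.drop(index=list(in_pattern))
        assert raw.q90.idxmax() == pause_pos
        assert raw.loc[pause_pos, "q90"] > 1.5 * background.q90.median()

    def test_strand_separation(self, pause_dataset):
        """A pattern and its reverse complement share no (site, read)
        contributions: pattern sites only aggregate same-strand reads."""
        cfg, motif, reference, reads, truth = pause_dataset
        fwd_sites = pw.find_sites(reference, motif)
        rev_sites = pw.find_sites(reference, pw.reverse_complement(motif))
        pairs_f = {(s.start, s.strand) for s in fwd_sites}
        pairs_r = {(s.start, s.strand) for s in rev_sites}
        assert pairs_f and pairs_r
        assert pairs_f.isdisjoint(pairs_r)
        # reverse-complement profile must not show the forward-strand pause
        prof_r = pw.extract_profiles(rev_sites, reads)
        raw_r = prof_r.data[prof_r.data.track == "raw"].set_index("position")
        # offset of the pause in the complementary pattern's frame
        assert raw_r.q90.max() < 2.0

    def test_null_profile_indistinguishable_from_background(self, null_dataset):
        """No pause process: in-pattern raw IPDs pass two-sided rank tests
        against the pooled background, family-wise alpha 0.01 (Bonferroni
        over the pattern positions)."""
        cfg, motif, reference, reads, truth = null_dataset
        assert truth.empty
        sites = pw.find_sites(reference, motif)
        prof = pw.extract_profiles(sites, reads)
        obs = _pooled_raw_observations(sites, reads, prof)
        pattern_positions = [
            p for p in range(prof.anchor, prof.anchor + len(motif)) if len(obs[p]) >= 5
        ]
        bg = np.concatenate(
            [obs[p] for p in range(prof.window) if p not in set(pattern_positions)]
        )
        assert pattern_positions
        for p in pattern_positions:
            pval = stats.mannwhitneyu(obs[p], bg, alternative="two-sided").pvalue
            assert pval > 0.01 / len(pattern_positions)

    def test_quantile_monotonicity(self, pause_dataset):
        cfg, motif, reference, reads, truth = pause_dataset
        sites = pw.find_sites(reference, motif)
        prof = pw.extract_profiles(sites, reads, quantile_levels=(0.5, 0.90, 0.95))
        well_covered = prof.data[prof.data["count"] >= 20]
        assert len(well_covered) > 0
        assert (well_covered.q95 >= well_covered.q90).all()
        assert (well_covered.q90 >= well_covered.q50).all()
        assert (well_covered.q90 >= 0).all()

    def test_palindromic_doubling_symmetry(self):
        """Forward and reverse profiles of a palindromic pattern on
        strand-symmetric simulated reads agree within Monte Carlo error."""
        cfg = pw.SimulationConfig(
            seed=3,
            reference_length=8_000,
            n_reads=600,
            read_length=(1001, 1600),
            motifs=(("CGCGCGCGCG", 2_500), ("CGCGCGCGCG", 5_500)),
            pauses=(pw.PauseSpec(offset=0, p_pause=0.2, tau_seconds=3.0),),
        )
        reference, reads, truth = pw.simulate_dataset(cfg)
        sites = pw.find_sites(reference, "CGCGCGCGCG")
        fwd = [s for s in sites if s.strand == "+"]
        rev = [s for s in sites if s.strand == "-"]
        assert len(fwd) == len(rev) >= 2
        pf = pw.extract_profiles(fwd, reads)
        pr = pw.extract_profiles(rev, reads)
        mf = pf.data[pf.data.track == "raw"].set_index("position")["mean"]
        mr = pr.data[pr.data.track == "raw"].set_index("position")["mean"]
        in_pat = list(range(pf.anchor, pf.anchor + 10))
        np.testing.assert_allclose(mf[in_pat], mr[in_pat], atol=0.6)

    def test_window_shorter_than_pattern_rejected(self):
        site = pw.PatternSite("r", 0, 20, "+", "A" * 20)
        with pytest.raises(ValidationError):
            pw.extract_profiles([site], [], window=16)

    def test_zero_reads_gives_empty_profile(self):
        site = pw.PatternSite("r", 10, 14, "+", "ACGT")
        prof = pw.extract_profiles([site], [], window=16)
        assert (prof.data["count"] == 0).all()
        assert prof.n_reads == 0


def _pooled_raw_observations(sites, reads, prof):
    """Collect per-window-position raw IPD values the same way the profiler
    pools them (independent reimplementation for the rank test)."""
    obs = {p: [] for p in range(prof.window)}
    for site in sites:
        a = prof.anchor
        for read in reads:
            if read.strand != site.strand:
                continue
            for p in range(prof.window):
                if site.strand == "+":
                    f = site.start - a + p
                    t = f - read.reference_start
                else:
                    f = (site.end - 1) + a - p
                    t = (read.reference_start + len(read) - 1) - f
                if 0 <= t < len(read):
                    obs[p].append(read.ipd_seconds[t])
    return {p: np.asarray(v) for p, v in obs.items()}


class TestExportProfile:
    def test_round_trip(self, tmp_path, pause_dataset):
        cfg, motif, reference, reads, truth = pause_dataset
        sites = pw.find_sites(reference, motif)
        prof = pw.extract_profiles(sites, reads, window=64)
        f = tmp_path / "profile.tsv"
        pw.export_profile(prof, f)
        back = pw.load_profile(f)
        assert back.window == 64
        a, b = prof.data.reset_index(drop=True), back.data.reset_index(drop=True)
        for col in ("position", "count", "low_count"):
            assert (a[col] == b[col]).all()
        for col in ("mean", "q90", "q95"):
            np.testing.assert_allclose(a[col], b[col], rtol=1e-4, equal_nan=True)

    def test_empty_profile_header_only_rows(self, tmp_path):
        prof = pw.extract_profiles([], [], window=8)
        f = tmp_path / "profile.tsv"
        pw.export_profile(prof, f)
        lines = f.read_text().splitlines()
        assert lines[0].startswith("position\ttrack\tcount")
        assert all(line.split("\t")[2] == "0" for line in lines[1:])

    def test_low_count_flagging(self):
        site = pw.PatternSite("r", 4, 8, "+", "CCCC")
        reads = [make_read("r1", 0, "AAAACCCCGGGG")]
        prof = pw.extract_profiles([site], reads, window=12, anchor=4, min_count=2)
        raw = prof.data[prof.data.track == "raw"]
        assert (raw.low_count == 1).all()  # single read never reaches 2

    def test_render_profile_writes_figure(self, tmp_path, pause_dataset):
        cfg, motif, reference, reads, truth = pause_dataset
        sites = pw.find_sites(reference, motif)
        prof = pw.extract_profiles(sites, reads, window=64)
        out = tmp_path / "p.png"
        pw.render_profile(prof, out)
        assert out.stat().st_size > 0
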