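import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from bordersdm.binning import cpm_normalize
from bordersdm.config import SlideConfig
from bordersdm.profiles import (
    distant_reference,
    gradient_summary,
    layer_composition,
    signature_score,
)
from bordersdm.sdm import digitize_slide
from bordersdm.synth import BorderSpec, generate_slide


def toy_assignment():
    """12 spots, hand-checkable: layer -1 holds 10 spots (2 macrophages)."""
    rows = []
    for i in range(10):
        rows.append(("s%d" % i, "-1", "1", "macrophage" if i < 2 else "malignant"))
    rows.append(("s10", "+1", "1", "hepatocyte"))
    rows.append(("s11", "none", "none", "B"))
    df = pd.DataFrame(rows, columns=["spot_id", "layer", "tile", "cell_type"])
    df["x_um"] = 0.0
    df["y_um"] = 0.0
    df["d_um"] = np.where(df["layer"] == "-1", -100.0, 100.0)
    return df


class TestLayerComposition:
    def test_simple_fraction(self):
        prof = layer_composition(toy_assignment(), denominator="all")
        row = prof.query("layer == '-1' and cell_type == 'macrophage'").iloc[0]
        assert row["fraction"] == pytest.approx(0.2)
        assert row["n_denominator"] == 10

    def test_nonparenchymal_denominator(self):
        prof = layer_composition(toy_assignment(), denominator="nonparenchymal")
        row = prof.query("layer == '-1' and cell_type == 'macrophage'").iloc[0]
        # the 8 malignant spots leave the denominator entirely
        assert row["fraction"] == pytest.approx(1.0)

    def test_fractions_sum_to_one_per_layer(self):
        prof = layer_composition(toy_assignment(), denominator="all")
        sums = prof.dropna(subset=["fraction"]).groupby("layer")["fraction"].sum()
        np.testing.assert_allclose(sums, 1.0)

    def test_empty_layer_flagged_nan(self):
        prof = layer_composition(toy_assignment(), denominator="all")
        empty = prof[prof["layer"] == "+3"]
        assert empty["fraction"].isna().all()
        assert (empty["n_denominator"] == 0).all()

    def test_subtype_split_avoids_double_counting(self):
        df = toy_assignment()
        df["subtype"] = pd.NA
        df.loc[df["cell_type"] == "macrophage", "cell_type"] = "T/NK"
        df.loc[df.index[:1], "subtype"] = "exhausted-T"
        prof = layer_composition(df, denominator="all", use_subtypes=True)
        p = prof.set_index(["layer", "cell_type"])["fraction"]
        assert p.loc[("-1", "exhausted-T")] == pytest.approx(0.1)
        assert p.loc[("-1", "T/NK")] == pytest.approx(0.1)

    def test_bad_denominator_rejected(self):
        with pytest.raises(ValueError):
            layer_composition(toy_assignment(), denominator="wrong")


class TestGradientSummary:
    def test_identical_slides_give_na_tests(self):
        prof = layer_composition(toy_assignment(), denominator="all")
        stacked = pd.concat(
            [prof.assign(slide_id=s) for s in ("a", "b", "c")], ignore_index=True
        )
        out = gradient_summary(stacked, "macrophage", layers=("-1", "+1"))
        assert out.loc[out["layer"] == "-1", "sd"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(out.loc[out["layer"] == "-1", "t_next"].iloc[0])

    def test_planted_gradient_direction_across_slides(self):
        profiles = []
        for i in range(6):
            cfg = SlideConfig(slide_extent_um=(3000.0, 3000.0))
            slide = generate_slide(
                config=cfg, border=BorderSpec(amplitude_um=200.0, period_um=3000.0,
                                              phase=i * 0.9),
                seed=100 + i, with_expression=False,
            )
            _, _, _, _, assignment = digitize_slide(
                slide.truth, slide_extent_um=cfg.slide_extent_um, n_tiles=20
            )
            profiles.append(
                layer_composition(assignment, denominator="all").assign(slide_id=i)
            )
        stacked = pd.concat(profiles, ignore_index=True)
        mac = stacked[stacked["cell_type"] == "macrophage"]
        per_slide = mac.pivot(index="slide_id", columns="layer", values="fraction")
        assert ((per_slide["-1"] - per_slide["-3"]) > 0).sum() >= 5
        out = gradient_summary(stacked, "macrophage")
        assert out.loc[out["layer"] == "-1", "mean"].iloc[0] > \
               out.loc[out["layer"] == "-3", "mean"].iloc[0]

    def test_null_difference_not_significant(self):
        rng = np.random.default_rng(0)
        rows = []
        for s in range(10):
            for layer in ("-1", "-2"):
                rows.append({"slide_id": s, "layer": layer, "cell_type": "B",
                             "fraction": rng.normal(0.1, 0.01)})
        out = gradient_summary(pd.DataFrame(rows), "B", layers=("-1", "-2"))
        assert out.loc[out["layer"] == "-1", "p_next"].iloc[0] > 0.01


class TestSignatureScore:
    def _units(self, X, genes):
        adata = ad.AnnData(X=sparse.csr_matrix(np.asarray(X, float)),
                           var=pd.DataFrame(index=genes))
        cpm_normalize(adata)
        return adata

    def test_whole_transcriptome_scores_zero(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(8)]
        units = self._units(rng.poisson(20, (15, 8)) + 1, genes)
        score = signature_score(units, genes)
        # per-gene z-columns centre on zero; their mean over the whole
        # transcriptome nearly cancels for every unit
        assert np.abs(score).max() < 0.2
        assert score.mean() == pytest.approx(0.0, abs=1e-9)

    def test_spiked_unit_has_max_score(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(10)]
        X = rng.poisson(20, (12, 10)).astype(float) + 1
        X[4, :3] *= 30
        units = self._units(X, genes)
        score = signature_score(units, ["g0", "g1", "g2"])
        assert score.argmax() == 4

    def test_absent_set_and_single_unit_rejected(self):
        genes = ["a", "b"]
        units = self._units([[1, 2], [3, 4]], genes)
        with pytest.raises(ValueError, match="absent"):
            signature_score(units, ["zz"])
        single = self._units([[1, 2]], genes)
        with pytest.raises(ValueError, match="2 units"):
            signature_score(single, ["a"])

    def test_saa_program_higher_in_first_paratumor_layer(self, small_adata,
                                                         small_slide,
                                                         expression_model):
        truth = small_slide.truth.set_index("spot_id").loc[small_adata.obs_names]
        hep = (truth["cell_type"] == "hepatocyte").to_numpy()
        score = signature_score(small_adata[hep], expression_model.gs1)
        layers = truth.loc[hep, "layer_truth"].to_numpy()
        assert score[layers == "+1"].mean() > score[layers == "+3"].mean()


class TestDistantReference:
    def test_both_sides_present_for_central_border(self):
        cfg = SlideConfig(slide_extent_um=(6000.0, 6000.0))
        slide = generate_slide(config=cfg, border=BorderSpec(kind="straight"),
                               seed=1, with_expression=False)
        _, _, _, _, assignment = digitize_slide(
            slide.truth, slide_extent_um=cfg.slide_extent_um, tile_labels=[]
        )
        out = distant_reference(assignment)
        assert out["present"] == {"tumor": True, "paratumor": True}
        frac = out["profiles"]["tumor"].set_index("cell_type")["fraction"]
        # distant tumor band recovers the planted baseline composition
        assert frac["macrophage"] == pytest.approx(0.030, abs=0.01)

    def test_missing_side_flagged(self):
        cfg = SlideConfig(slide_extent_um=(4000.0, 4000.0))
        slide = generate_slide(
            config=cfg, border=BorderSpec(kind="straight", y_offset_um=1000.0),
            seed=1, with_expression=False,
        )
        _, _, _, _, assignment = digitize_slide(
            slide.truth, slide_extent_um=cfg.slide_extent_um, tile_labels=[]
        )
        out = distant_reference(assignment)
        # border at y=1000: only 1 mm of tumor-side tissue, so no distant band
        assert out["present"]["tumor"] is False
        assert out["profiles"]["tumor"] is None
        assert out["present"]["paratumor"] is True
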