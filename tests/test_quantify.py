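"""Nuclear quantification: exactness, normalization, summaries, variation."""

import numpy as np
import pandas as pd
import pytest

from samquant import (
    ImageStack,
    LabelMask,
    RegionSpec,
    SamQuantError,
    build_parabolic_mask,
    build_partition,
    build_rectangular_mask,
    combine_masks,
    intensity_variation,
    normalize_cohort,
    quantify_nuclei,
    summarize_cohort,
    summarize_meristem,
    true_model,
)
from conftest import small_spec


@pytest.fixture(scope="module")
def flat_partition():
    """Partition over a small raster where everything is tissue (PZ/RM),
    convenient for handcrafted label masks."""
    spec = small_spec()
    model = true_model(spec)
    px = spec.pixel_size_um
    tissue = combine_masks(
        build_parabolic_mask(model, spec.image_shape, px),
        build_rectangular_mask(model, spec.image_shape, px),
    )
    return build_partition(model, RegionSpec(), tissue, px)


def make_stack(img, px=0.7, names=("FD",)):
    data = np.asarray(img, dtype=np.float64)[np.newaxis, np.newaxis]
    if len(names) > 1:
        data = np.repeat(data, len(names), axis=0)
    return ImageStack(data, px, channel_names=list(names))


class TestQuantifyNuclei:
    def test_uniform_nucleus(self, flat_partition):
        img = np.zeros((160, 160))
        labels = np.zeros((160, 160), int)
        labels[40:42, 78:83] = 1  # 10 px
        img[labels == 1] = 5.0
        df = quantify_nuclei(make_stack(img), LabelMask(labels), flat_partition)
        assert df.loc[0, "total_FD"] == 50.0
        assert df.loc[0, "concentration_FD"] == 5.0
        assert df.loc[0, "area_px"] == 10

    def test_zero_intensity_single_pixel(self, flat_partition):
        labels = np.zeros((160, 160), int)
        labels[50, 80] = 3
        df = quantify_nuclei(
            make_stack(np.zeros((160, 160))), LabelMask(labels), flat_partition
        )
        assert df.loc[0, "total_FD"] == 0.0 and df.loc[0, "concentration_FD"] == 0.0

    def test_matches_brute_force_pixel_oracle(self, clean_scene, region_spec):
        """Vectorized sums equal an explicit per-pixel loop bit-exactly
        and equal the generative truth exactly."""
        truth, stack, mask = clean_scene
        px = truth.spec.pixel_size_um
        tissue = combine_masks(
            build_parabolic_mask(truth.model, truth.spec.image_shape, px),
            build_rectangular_mask(truth.model, truth.spec.image_shape, px),
        )
        partition = build_partition(truth.model, region_spec, tissue, px)
        df = quantify_nuclei(stack, mask, partition).set_index("nucleus_id")
        for n in truth.nuclei:
            for ci, ch in enumerate(stack.channel_names):
                brute = 0.0
                img = stack.data[ci, 0]
                for r, c in zip(*n.pixels):
                    brute += img[r, c]
                assert df.loc[n.nucleus_id, f"total_{ch}"] == brute
                assert df.loc[n.nucleus_id, f"total_{ch}"] == n.total_intensity[ch]
                assert df.loc[n.nucleus_id, f"concentration_{ch}"] == n.concentration[ch]

    def test_split_label_additivity(self, flat_partition):
        """Splitting one label into two covering the same pixels leaves
        the summed totals exactly unchanged."""
        rng = np.random.default_rng(5)
        img = rng.integers(0, 4096, (160, 160)).astype(float)
        whole = np.zeros((160, 160), int)
        whole[40:46, 76:84] = 1
        split = whole.copy()
        split[43:46, 76:84] = 2
        df1 = quantify_nuclei(make_stack(img), LabelMask(whole), flat_partition)
        df2 = quantify_nuclei(make_stack(img), LabelMask(split), flat_partition)
        assert df2["total_FD"].sum() == df1["total_FD"].sum()
        assert df2["area_px"].sum() == df1["area_px"].sum()

    def test_shape_mismatch_rejected(self, flat_partition):
        with pytest.raises(SamQuantError, match="shape"):
            quantify_nuclei(
                make_stack(np.zeros((64, 64))),
                LabelMask(np.zeros((160, 160), int)),
                flat_partition,
            )

    def test_multi_z_rejected(self, flat_partition):
        data = np.zeros((1, 3, 160, 160))
        with pytest.raises(SamQuantError, match="single-z"):
            quantify_nuclei(
                ImageStack(data, 0.7), LabelMask(np.ones((160, 160), int)), flat_partition
            )


class TestNormalizeCohort:
    def frame(self, concentrations, region="PZ"):
        return pd.DataFrame(
            {
                "meristem_id": "m0",
                "time_point": "10LD",
                "nucleus_id": range(1, len(concentrations) + 1),
                "region": region,
                "concentration_FD": concentrations,
            }
        )

    def test_simple_scaling(self):
        df = normalize_cohort(self.frame([2.0, 4.0, 8.0]))
        assert df["normalized_FD"].tolist() == [0.25, 0.5, 1.0]

    def test_channels_normalized_independently(self):
        df = self.frame([1.0, 2.0])
        df["concentration_FT"] = [5.0, 10.0]
        out1 = normalize_cohort(df)
        df_scaled = df.copy()
        df_scaled["concentration_FT"] *= 10
        out2 = normalize_cohort(df_scaled)
        assert out1["normalized_FD"].tolist() == out2["normalized_FD"].tolist()

    def test_idempotent(self):
        df = normalize_cohort(self.frame([3.0, 9.0]))
        df2 = df.copy()
        df2["concentration_FD"] = df["normalized_FD"]
        out = normalize_cohort(df2)
        assert out["normalized_FD"].tolist() == df["normalized_FD"].tolist()

    def test_all_zero_channel_warns(self):
        with pytest.warns(UserWarning, match="no positive"):
            out = normalize_cohort(self.frame([0.0, 0.0]))
        assert (out["normalized_FD"] == 0).all()

    def test_outside_records_excluded_from_max(self):
        df = pd.concat(
            [self.frame([2.0, 4.0]), self.frame([100.0], region="OUTSIDE")],
            ignore_index=True,
        )
        out = normalize_cohort(df)
        assert out.loc[1, "normalized_FD"] == 1.0  # max among tissue records


class TestSummaries:
    def records(self, values):
        return normalize_cohort(
            pd.DataFrame(
                {
                    "meristem_id": "m0",
                    "time_point": "11LD",
                    "nucleus_id": range(1, len(values) + 1),
                    "region": "RM",
                    "concentration_FD": values,
                }
            )
        )

    def test_closed_form_quartiles(self):
        # {1,2,3} normalized to {1/3, 2/3, 1}: median 2/3, IQR [0.5, 5/6]
        summ = summarize_meristem(self.records([1.0, 2.0, 3.0]))
        row = summ[(summ.region == "RM")].iloc[0]
        assert row["median"] == pytest.approx(2 / 3)
        assert row["q1"] == pytest.approx(0.5)
        assert row["q3"] == pytest.approx(5 / 6)
        assert row["q1"] <= row["median"] <= row["q3"]

    def test_single_value_collapses(self):
        summ = summarize_meristem(self.records([4.0]))
        row = summ[summ.region == "RM"].iloc[0]
        assert row["median"] == row["q1"] == row["q3"] == 1.0

    def test_median_matches_sort_oracle(self, rng):
        values = rng.random(1001) * 50
        summ = summarize_meristem(self.records(values))
        normalized = np.sort(values / values.max())
        assert summ[summ.region == "RM"].iloc[0]["median"] == normalized[500]

    def test_empty_regions_emitted_with_zero_count(self):
        summ = summarize_meristem(self.records([1.0, 2.0]))
        cz = summ[summ.region == "CZ"].iloc[0]
        assert cz["n_nuclei"] == 0 and np.isnan(cz["median"])

    def test_cohort_summary_one_block_per_meristem(self, rng):
        a = self.records(rng.random(5))
        b = self.records(rng.random(5)).assign(meristem_id="m1")
        summ = summarize_cohort(pd.concat([a, b], ignore_index=True))
        assert set(summ["meristem_id"]) == {"m0", "m1"}

    def test_unnormalized_input_rejected(self):
        raw = pd.DataFrame(
            {
                "meristem_id": "m0",
                "time_point": "",
                "nucleus_id": [1],
                "region": "RM",
                "concentration_FD": [1.0],
            }
        )
        with pytest.raises(SamQuantError, match="normalize"):
            summarize_meristem(raw)


class TestIntensityVariation:
    def test_uniform_profile_is_zero(self):
        assert intensity_variation([2, 2, 2, 2]) == 0.0

    def test_two_point_profile(self):
        assert intensity_variation([1, 3]) == 0.5

    def test_punctate_exceeds_diffuse_at_equal_total(self):
        punctate = [1, 1, 20, 1, 1]  # total 24, one bright spike
        diffuse = [4.8] * 5  # same total, even spread
        assert intensity_variation(punctate) > intensity_variation(diffuse)

    def test_errors(self):
        with pytest.raises(SamQuantError):
            intensity_variation([5.0])
        with pytest.raises(SamQuantError):
            intensity_variation([0.0, 0.0])
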