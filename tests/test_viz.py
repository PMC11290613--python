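"""Rendering contracts: color orientation, histogram pass-through, exports."""

import json
import re

import numpy as np
import pytest

from survcontour.cox import fit_cox
from survcontour.data import summarize_covariate
from survcontour.errors import ConsistencyError, FormatError
from survcontour.surface import SurvivalSurface, build_grid, compute_surface
from survcontour.viz import RenderOptions, export, render_contour2d, render_surface3d


@pytest.fixture
def cox_surface(ph_dataset):
    fit = fit_cox(ph_dataset)
    return compute_surface(fit, build_grid(ph_dataset, n_points=25))


@pytest.fixture
def summary(ph_dataset):
    return summarize_covariate(ph_dataset, "x", n_bins=15)


def _constant_surface(value=0.5):
    return SurvivalSurface(
        time_grid=np.array([0.0, 1.0, 2.0]),
        covariate_values=np.array([0.0, 0.5, 1.0]),
        values=np.full((3, 3), value),
        outcome_type="survival",
    )


def _luminance(hexcolor):
    r, g, b = (int(hexcolor[i:i + 2], 16) / 255 for i in (1, 3, 5))
    return 0.2126 * r + 0.7152 * g + 0.0722 * b


class TestContour2D:
    def test_histogram_counts_pass_through_exactly(self, cox_surface, summary):
        art = render_contour2d(cox_surface, summary)
        assert art.payload["histogram"] == [list(b) for b in summary.histogram]
        # and the drawn bars match too
        axh = art.figure.axes[1]
        widths = sorted(p.get_width() for p in axh.patches)
        assert widths == sorted(float(b[2]) for b in summary.histogram)
        art.close()

    def test_covariate_mismatch_rejected(self, cox_surface, ph_dataset):
        other = summarize_covariate(ph_dataset, "x")
        object.__setattr__(other, "column", "somethingelse")
        with pytest.raises(ConsistencyError):
            render_contour2d(cox_surface, other)

    def test_constant_surface_single_band(self):
        art = render_contour2d(_constant_surface(0.5), None)
        vals = np.asarray(art.payload["surface"]["values"])
        bands = {int(v // art.payload["options"]["level_step"]) for v in vals.ravel()}
        assert len(bands) == 1  # one flat color region
        # the color legend spans the full [0, 1] probability range
        step = art.payload["options"]["level_step"]
        assert len(art.payload["colors"]["band_colors"]) == round(1 / step)
        art.close()

    def test_level_sets_monotone_for_positive_beta(self, ph_dataset):
        """With a harmful predictor, each survival level is reached earlier
        for higher covariate values (contour lines slope down in time)."""
        fit = fit_cox(ph_dataset)
        assert fit.beta[0] > 0
        surf = compute_surface(fit, build_grid(ph_dataset, n_points=40), ci_level=None)
        # level-set crossing time per row, extracted from the matrix
        for level in (0.8, 0.6, 0.4):
            crossing = []
            for row in surf.values:
                idx = np.argmax(row < level)
                crossing.append(surf.time_grid[idx] if row.min() < level else np.inf)
            crossing = np.asarray(crossing)
            finite = np.isfinite(crossing)
            assert np.all(np.diff(crossing[finite]) <= 1e-9)

    def test_incidence_scale_reversed_so_darker_is_worse(self, cox_surface):
        art_s = render_contour2d(cox_surface, None)
        inc = _constant_surface(0.3)
        inc.outcome_type = "cumulative_incidence"
        art_i = render_contour2d(inc, None)
        lum_s = [_luminance(c) for c in art_s.payload["colors"]["band_colors"]]
        lum_i = [_luminance(c) for c in art_i.payload["colors"]["band_colors"]]
        # survival: low value (bad) dark -> luminance increasing
        assert all(np.diff(lum_s) > 0)
        # incidence: high value (bad) dark -> luminance decreasing
        assert all(np.diff(lum_i) < 0)
        art_s.close(); art_i.close()


class TestSurface3D:
    def test_without_bands_single_layer(self):
        art = render_surface3d(_constant_surface(0.5))
        assert len(art.payload["layers"]) == 1
        assert art.payload["layers"][0]["opacity"] == 1.0
        art.close()

    def test_with_bands_three_layers_middle_opaque(self, cox_surface):
        assert cox_surface.has_bands
        art = render_surface3d(cox_surface, RenderOptions(ci_opacity=0.25))
        ops = [l["opacity"] for l in art.payload["layers"]]
        assert ops == [0.25, 1.0, 0.25]
        art.close()

    def test_html_self_contained(self, cox_surface, tmp_path):
        art = render_surface3d(cox_surface)
        p = export(art, tmp_path / "s3d.html")
        text = p.read_text()
        assert p.stat().st_size > 0
        assert "survcontour-data" in text
        # no network fetches of any kind
        assert not re.search(r'(src|href)\s*=\s*["\']https?://', text)
        art.close()


class TestExport:
    def test_html_png_svg(self, cox_surface, summary, tmp_path):
        art = render_contour2d(cox_surface, summary)
        for name in ("f.html", "f.png", "f.svg"):
            p = export(art, tmp_path / name, dpi=100)
            assert p.stat().st_size > 0
        art.close()

    def test_png_has_plausible_dimensions(self, cox_surface, tmp_path):
        from PIL import Image
        art = render_contour2d(cox_surface, None)
        p = export(art, tmp_path / "f.png", dpi=150)
        with Image.open(p) as im:
            w, h = im.size
        assert w == 9 * 150 and h > 300  # 9-inch figure at dpi 150
        art.close()

    def test_format_extension_conflict(self, cox_surface, tmp_path):
        art = render_contour2d(cox_surface, None)
        with pytest.raises(FormatError):
            export(art, tmp_path / "f.html", format="png")
        with pytest.raises(FormatError):
            export(art, tmp_path / "f.pdf")
        art.close()

    def test_svg_deterministic(self, ph_dataset, tmp_path):
        def make():
            fit = fit_cox(ph_dataset)
            surf = compute_surface(fit, build_grid(ph_dataset, n_points=20))
            summ = summarize_covariate(ph_dataset, "x", n_bins=10)
            art = render_contour2d(surf, summ)
            out = export(art, tmp_path / f"svg{make.count}.svg")
            make.count += 1
            art.close()
            return out.read_bytes()
        make.count = 0
        assert make() == make()
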