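"""Vector-to-raster conversion, composition and representativeness."""

import json
import math

import numpy as np
import pytest
from shapely.geometry import LineString, box

from guildscape.landscape import (CategoricalRaster, HabitatVectorMap,
                                  SamplePlot, buffer_lines, composition,
                                  rasterize, read_ascii_grid, read_geojson,
                                  read_geotiff, read_plots_csv,
                                  representativeness, write_ascii_grid,
                                  write_geotiff, write_plots_csv)

from _naive import spearman_rho


def test_buffer_area_matches_analytic_formula():
    line = LineString([(0, 0), (100, 0)])
    (poly, code), = buffer_lines([(line, 4)], 5.0)
    assert code == 4
    # rectangle 100 x 10 plus two round caps = a pi*25 disc
    assert poly.area == pytest.approx(100 * 10 + math.pi * 25, rel=1e-3)


def test_buffer_skips_degenerate_lines(caplog):
    line = LineString([(5, 5), (5, 5)])
    with caplog.at_level("WARNING"):
        assert buffer_lines([(line, 1)], 5.0) == []
    assert "zero-length" in caplog.text


def test_buffer_empty_list_is_identity():
    assert buffer_lines([], 5.0) == []


def test_rasterize_single_polygon_fills_grid():
    vmap = HabitatVectorMap([(box(0, 0, 50, 50), 3)], [])
    r = rasterize(vmap, 10.0)
    assert r.shape == (5, 5)
    assert (r.values == 3).all()


def test_rasterize_dominant_class_wins():
    # cell [0,10)x[0,10): class 1 covers 60%, class 2 covers 40%
    vmap = HabitatVectorMap([(box(0, 0, 6, 10), 1), (box(6, 0, 10, 10), 2)], [])
    r = rasterize(vmap, 10.0)
    assert r.shape == (1, 1)
    assert r.values[0, 0] == 1


def test_rasterize_tie_goes_to_lowest_code():
    vmap = HabitatVectorMap([(box(0, 0, 5, 10), 7), (box(5, 0, 10, 10), 2)], [])
    r = rasterize(vmap, 10.0)
    assert r.values[0, 0] == 2


def test_buffered_line_cuts_strip_through_field():
    field = box(0, 0, 100, 100)
    hedge = LineString([(0, 55), (100, 55)])  # along a cell-centre row
    vmap = HabitatVectorMap([(field, 1)], [(hedge, 9)])
    r = rasterize(vmap, 10.0, line_priority=True)
    strip_rows = np.nonzero((r.values == 9).any(axis=1))[0]
    assert len(strip_rows) == 1  # ~1-cell-wide strip
    assert (r.values[strip_rows[0]] == 9).all()
    # without line priority the full-coverage field polygon shadows the line
    r2 = rasterize(vmap, 10.0, line_priority=False)
    assert (r2.values == 9).sum() < (r.values == 9).sum()


def test_rasterize_empty_map_errors():
    with pytest.raises(ValueError, match="empty"):
        rasterize(HabitatVectorMap([], []), 10.0)


def test_rasterize_area_conservation():
    # |vector proportion - raster proportion| <= perimeter*cell / total area
    vmap = HabitatVectorMap([(box(0, 0, 63, 100), 1), (box(63, 0, 100, 100), 2)], [])
    r = rasterize(vmap, 10.0)
    comp = composition(r)
    bound = 2 * (100 + 63) * 10.0 / (100 * 100)
    assert abs(comp[1] - 0.63) <= bound


def test_composition_counts(two_class_raster):
    comp = composition(two_class_raster)
    assert comp == {1: 0.5, 2: 0.5}
    assert sum(comp.values()) == pytest.approx(1.0, abs=1e-9)


def test_composition_with_mask_partition(rng):
    v = rng.integers(1, 4, size=(50, 50))
    r = CategoricalRaster(v, 10.0)
    top = np.zeros((50, 50), dtype=bool)
    top[:20] = True
    whole = composition(r)
    a, b = composition(r, top), composition(r, ~top)
    for c in whole:
        mix = (a.get(c, 0) * 20 + b.get(c, 0) * 30) / 50
        assert whole[c] == pytest.approx(mix, abs=1e-12)


def test_composition_all_nodata_errors(uniform_raster):
    with pytest.raises(ValueError):
        composition(uniform_raster, mask=np.zeros((10, 10), dtype=bool))


def test_representativeness_identity(rng):
    v = rng.integers(1, 5, size=(30, 30))
    r = CategoricalRaster(v, 10.0)
    plot = SamplePlot("all", (150.0, 150.0), 1e4)  # covers everything
    res = representativeness(r, [plot])
    assert res.rho == pytest.approx(1.0)


def test_representativeness_matches_rank_oracle(rng):
    v = rng.integers(1, 6, size=(40, 40))
    r = CategoricalRaster(v, 10.0)
    plots = [SamplePlot(f"p{i}", (50.0 + 100 * i, 200.0), 60.0) for i in range(3)]
    res = representativeness(r, plots)
    whole = composition(r)
    union = np.zeros(r.shape, dtype=bool)
    for p in plots:
        union |= r.circle_mask(p.centre, p.radius)
    inside = composition(r, union)
    codes = sorted(whole)
    oracle = spearman_rho([whole[c] for c in codes],
                          [inside.get(c, 0.0) for c in codes])
    assert res.rho == pytest.approx(oracle, abs=1e-12)


def test_representativeness_needs_three_classes(uniform_raster):
    with pytest.raises(ValueError, match="3"):
        representativeness(uniform_raster, [SamplePlot("p", (50, 50), 30.0)])


def test_ascii_grid_roundtrip(tmp_path, rng):
    r = CategoricalRaster(rng.integers(1, 5, size=(7, 9)), 10.0,
                          origin=(100.0, 200.0))
    path = tmp_path / "grid.asc"
    write_ascii_grid(path, r)
    back = read_ascii_grid(path)
    assert (back.values == r.values).all()
    assert back.cell_size == r.cell_size
    assert back.origin == r.origin


def test_geotiff_roundtrip(tmp_path, rng):
    r = CategoricalRaster(rng.integers(1, 5, size=(6, 8)), 10.0,
                          origin=(500.0, 700.0))
    path = tmp_path / "grid.tif"
    write_geotiff(path, r)
    back = read_geotiff(path)
    assert (back.values == r.values).all()
    assert back.cell_size == r.cell_size
    assert back.origin == pytest.approx(r.origin)


def test_geojson_reader(tmp_path):
    fc = {"type": "FeatureCollection", "features": [
        {"type": "Feature", "properties": {"class_code": 1},
         "geometry": {"type": "Polygon",
                      "coordinates": [[[0, 0], [100, 0], [100, 100], [0, 100], [0, 0]]]}},
        {"type": "Feature", "properties": {"class_code": 9},
         "geometry": {"type": "LineString", "coordinates": [[0, 50], [100, 50]]}},
    ]}
    path = tmp_path / "map.geojson"
    path.write_text(json.dumps(fc))
    vmap = read_geojson(path)
    assert len(vmap.polygons) == 1 and len(vmap.lines) == 1
    assert vmap.lines[0][1] == 9


def test_plots_csv_roundtrip(tmp_path):
    plots = [SamplePlot("A1", (100.0, 200.0), 250.0),
             SamplePlot("A2", (600.0, 200.0), 250.0)]
    path = tmp_path / "plots.csv"
    write_plots_csv(path, plots)
    back = read_plots_csv(path)
    assert [p.plot_id for p in back] == ["A1", "A2"]
    assert back[0].centre == (100.0, 200.0) and back[0].radius == 250.0
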