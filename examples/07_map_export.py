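"""Export a county frailty field as a choropleth-ready GeoJSON.

Uses synthetic square polygons (packaged stand-ins for real boundaries);
each feature carries the county value and its quantile class.
"""

import json

import pandas as pd

from geoaft import make_county_graph, sample_icar_frailty
from geoaft.io import export_county_geojson, synthetic_geometry

graph = make_county_graph(layout="pa_fixture")
frailty = pd.Series(sample_icar_frailty(graph, tau=4.0, seed=3),
                    index=graph.nodes)

geom = synthetic_geometry(graph.nodes)
doc, report = export_county_geojson(frailty, geom, n_classes=5)
print(f"{len(doc['features'])} features; id mismatches: {report}")
classes = pd.Series([f["properties"]["quantile_class"]
                     for f in doc["features"]])
print("counties per quantile class:", classes.value_counts().sort_index().to_dict())
print("first feature:",
      json.dumps(doc["features"][0]["properties"], indent=2))
# Five quantile classes over 67 counties -> 13-14 counties per class;
# higher class = higher frailty = longer disease-specific survival.
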