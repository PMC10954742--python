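{
  "type": "FeatureCollection",
  "name": "eez_synthetic",
  "description": "SYNTHETIC, heavily simplified stand-in polygons (convex-box grade) approximating each Mediterranean country's EEZ footprint, for testing and examples. Not the Marine Regions geodatabase; load real EEZ GeoJSON for faithful geography.",
  "features": [
    {"type": "Feature", "properties": {"country": "IL"}, "geometry": {"type": "Polygon", "coordinates": [[[33.4, 31.3], [35.2, 31.3], [35.2, 33.1], [33.4, 33.1], [33.4, 31.3]]]}},
    {"type": "Feature", "properties": {"country": "PS"}, "geometry": {"type": "Polygon", "coordinates": [[[33.8, 31.1], [34.6, 31.1], [34.6, 31.7], [33.8, 31.7], [33.8, 31.1]]]}},
    {"type": "Feature", "properties": {"country": "EG"}, "geometry": {"type": "Polygon", "coordinates": [[[25.0, 31.0], [34.2, 31.0], [34.2, 32.6], [25.0, 32.6], [25.0, 31.0]]]}},
    {"type": "Feature", "properties": {"country": "LB"}, "geometry": {"type": "Polygon", "coordinates": [[[34.4, 33.1], [35.9, 33.1], [35.9, 34.7], [34.4, 34.7], [34.4, 33.1]]]}},
    {"type": "Feature", "properties": {"country": "SY"}, "geometry": {"type": "Polygon", "coordinates": [[[34.8, 34.7], [36.0, 34.7], [36.0, 36.0], [34.8, 36.0], [34.8, 34.7]]]}},
    {"type": "Feature", "properties": {"country": "CY"}, "geometry": {"type": "Polygon", "coordinates": [[[31.5, 33.8], [34.6, 33.8], [34.6, 36.0], [31.5, 36.0], [31.5, 33.8]]]}},
    {"type": "Feature", "properties": {"country": "TR"}, "geometry": {"type": "Polygon", "coordinates": [[[26.0, 35.3], [36.2, 35.3], [36.2, 37.0], [26.0, 37.0], [26.0, 35.3]]]}},
    {"type": "Feature", "properties": {"country": "GR"}, "geometry": {"type": "Polygon", "coordinates": [[[19.5, 34.0], [28.5, 34.0], [28.5, 39.6], [19.5, 39.6], [19.5, 34.0]]]}},
    {"type": "Feature", "properties": {"country": "LY"}, "geometry": {"type": "Polygon", "coordinates": [[[10.5, 31.0], [25.0, 31.0], [25.0, 34.4], [10.5, 34.4], [10.5, 31.0]]]}},
    {"type": "Feature", "properties": {"country": "TN"}, "geometry": {"type": "Polygon", "coordinates": [[[7.8, 33.2], [11.6, 33.2], [11.6, 38.2], [7.8, 38.2], [7.8, 33.2]]]}},
    {"type": "Feature", "properties": {"country": "MT"}, "geometry": {"type": "Polygon", "coordinates": [[[13.6, 35.0], [15.2, 35.0], [15.2, 36.4], [13.6, 36.4], [13.6, 35.0]]]}},
    {"type": "Feature", "properties": {"country": "IT"}, "geometry": {"type": "Polygon", "coordinates": [[[8.0, 36.2], [18.6, 36.2], [18.6, 44.0], [8.0, 44.0], [8.0, 36.2]]]}},
    {"type": "Feature", "properties": {"country": "AL"}, "geometry": {"type": "Polygon", "coordinates": [[[18.6, 39.6], [19.8, 39.6], [19.8, 41.9], [18.6, 41.9], [18.6, 39.6]]]}},
    {"type": "Feature", "properties": {"country": "ME"}, "geometry": {"type": "Polygon", "coordinates": [[[18.2, 41.6], [19.4, 41.6], [19.4, 42.6], [18.2, 42.6], [18.2, 41.6]]]}},
    {"type": "Feature", "properties": {"country": "HR"}, "geometry": {"type": "Polygon", "coordinates": [[[13.2, 42.3], [18.4, 42.3], [18.4, 45.6], [13.2, 45.6], [13.2, 42.3]]]}},
    {"type": "Feature", "properties": {"country": "ES"}, "geometry": {"type": "Polygon", "coordinates": [[[-5.4, 35.6], [3.4, 35.6], [3.4, 42.2], [-5.4, 42.2], [-5.4, 35.6]]]}},
    {"type": "Feature", "properties": {"country": "DZ"}, "geometry": {"type": "Polygon", "coordinates": [[[-2.2, 35.0], [8.6, 35.0], [8.6, 38.4], [-2.2, 38.4], [-2.2, 35.0]]]}}
  ]
}
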