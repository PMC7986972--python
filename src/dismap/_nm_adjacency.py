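"""Border-sharing adjacency for New Mexico's 33 counties.

Compiled from the county border map: one undirected edge per pair of
counties that share a common border. Corner-touching pairs recorded by the
Census county-adjacency convention are included.
"""

NM_COUNTIES = [
    "Bernalillo", "Catron", "Chaves", "Cibola", "Colfax", "Curry",
    "De Baca", "Dona Ana", "Eddy", "Grant", "Guadalupe", "Harding",
    "Hidalgo", "Lea", "Lincoln", "Los Alamos", "Luna", "McKinley",
    "Mora", "Otero", "Quay", "Rio Arriba", "Roosevelt", "San Juan",
    "San Miguel", "Sandoval", "Santa Fe", "Sierra", "Socorro", "Taos",
    "Torrance", "Union", "Valencia",
]

NM_BORDER_EDGES = [
    ("Bernalillo", "Cibola"),
    ("Bernalillo", "Sandoval"),
    ("Bernalillo", "Santa Fe"),
    ("Bernalillo", "Torrance"),
    ("Bernalillo", "Valencia"),
    ("Catron", "Cibola"),
    ("Catron", "Grant"),
    ("Catron", "Sierra"),
    ("Catron", "Socorro"),
    ("Chaves", "De Baca"),
    ("Chaves", "Eddy"),
    ("Chaves", "Lea"),
    ("Chaves", "Lincoln"),
    ("Chaves", "Otero"),
    ("Chaves", "Roosevelt"),
    ("Cibola", "McKinley"),
    ("Cibola", "Socorro"),
    ("Cibola", "Valencia"),
    ("Colfax", "Harding"),
    ("Colfax", "Mora"),
    ("Colfax", "Taos"),
    ("Colfax", "Union"),
    ("Curry", "De Baca"),
    ("Curry", "Quay"),
    ("Curry", "Roosevelt"),
    ("De Baca", "Guadalupe"),
    ("De Baca", "Lincoln"),
    ("De Baca", "Quay"),
    ("De Baca", "Roosevelt"),
    ("Dona Ana", "Luna"),
    ("Dona Ana", "Otero"),
    ("Dona Ana", "Sierra"),
    ("Eddy", "Lea"),
    ("Eddy", "Otero"),
    ("Grant", "Hidalgo"),
    ("Grant", "Luna"),
    ("Grant", "Sierra"),
    ("Guadalupe", "Lincoln"),
    ("Guadalupe", "Quay"),
    ("Guadalupe", "San Miguel"),
    ("Guadalupe", "Torrance"),
    ("Harding", "Mora"),
    ("Harding", "Quay"),
    ("Harding", "San Miguel"),
    ("Harding", "Union"),
    ("Hidalgo", "Luna"),
    ("Lincoln", "Otero"),
    ("Lincoln", "Socorro"),
    ("Lincoln", "Torrance"),
    ("Los Alamos", "Rio Arriba"),
    ("Los Alamos", "Sandoval"),
    ("Los Alamos", "Santa Fe"),
    ("Luna", "Sierra"),
    ("McKinley", "San Juan"),
    ("McKinley", "Sandoval"),
    ("Mora", "San Miguel"),
    ("Mora", "Santa Fe"),
    ("Mora", "Taos"),
    ("Otero", "Sierra"),
    ("Quay", "San Miguel"),
    ("Quay", "Union"),
    ("Rio Arriba", "San Juan"),
    ("Rio Arriba", "Sandoval"),
    ("Rio Arriba", "Santa Fe"),
    ("Rio Arriba", "Taos"),
    ("San Juan", "Sandoval"),
    ("San Miguel", "Santa Fe"),
    ("San Miguel", "Torrance"),
    ("Sandoval", "Santa Fe"),
    ("Santa Fe", "Torrance"),
    ("Sierra", "Socorro"),
    ("Socorro", "Torrance"),
    ("Socorro", "Valencia"),
    ("Torrance", "Valencia"),
]
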