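# Approximate queen-contiguity adjacency for the 67 Pennsylvania
# counties (fixture; curated, not derived from TIGER geometry).
42001	42041
42001	42055
42001	42133
42003	42005
42003	42007
42003	42019
42003	42125
42003	42129
42005	42019
42005	42031
42005	42063
42005	42065
42005	42129
42007	42019
42007	42073
42007	42125
42009	42013
42009	42021
42009	42057
42009	42061
42009	42111
42011	42029
42011	42071
42011	42075
42011	42077
42011	42091
42011	42107
42013	42021
42013	42027
42013	42033
42013	42061
42015	42081
42015	42113
42015	42115
42015	42117
42015	42131
42017	42077
42017	42091
42017	42095
42017	42101
42019	42031
42019	42073
42019	42085
42019	42121
42021	42033
42021	42063
42021	42111
42021	42129
42023	42033
42023	42035
42023	42047
42023	42083
42023	42105
42025	42077
42025	42079
42025	42089
42025	42095
42025	42107
42027	42033
42027	42035
42027	42061
42027	42087
42027	42119
42029	42045
42029	42071
42029	42091
42031	42053
42031	42065
42031	42121
42033	42035
42033	42047
42033	42063
42033	42065
42035	42081
42035	42105
42035	42119
42037	42079
42037	42081
42037	42093
42037	42097
42037	42107
42037	42113
42039	42049
42039	42085
42039	42121
42039	42123
42041	42043
42041	42055
42041	42099
42041	42133
42043	42071
42043	42075
42043	42097
42043	42099
42043	42107
42043	42133
42045	42091
42045	42101
42047	42053
42047	42065
42047	42083
42049	42123
42051	42059
42051	42111
42051	42125
42051	42129
42053	42065
42053	42121
42053	42123
42055	42057
42055	42061
42055	42099
42057	42061
42059	42125
42061	42067
42061	42087
42061	42099
42063	42065
42063	42129
42067	42087
42067	42099
42067	42109
42069	42079
42069	42089
42069	42115
42069	42127
42069	42131
42071	42075
42071	42133
42073	42085
42075	42107
42077	42091
42077	42095
42077	42107
42079	42089
42079	42107
42079	42113
42079	42131
42081	42093
42081	42097
42081	42113
42081	42117
42081	42119
42083	42105
42083	42123
42085	42121
42087	42109
42087	42119
42089	42095
42089	42103
42089	42127
42091	42101
42093	42097
42097	42107
42097	42109
42097	42119
42103	42127
42105	42117
42109	42119
42111	42129
42113	42131
42115	42127
42115	42131
42121	42123
42125	42129
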