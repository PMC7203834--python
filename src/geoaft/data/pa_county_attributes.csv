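# Pennsylvania 67-county fixture: region margins 15 urban non-Appalachia / 22 urban Appalachia / 30 rural Appalachia; 28-county catchment (9/9/10).
# RUCC codes and catchment membership are approximate fixture values.
fips,name,appalachia,rucc,catchment
42001,Adams,0,2,1
42003,Allegheny,1,1,0
42005,Armstrong,1,1,0
42007,Beaver,1,1,0
42009,Bedford,1,6,1
42011,Berks,0,2,1
42013,Blair,1,3,1
42015,Bradford,1,5,0
42017,Bucks,0,1,0
42019,Butler,1,1,0
42021,Cambria,1,3,1
42023,Cameron,1,9,0
42025,Carbon,1,2,1
42027,Centre,1,3,1
42029,Chester,0,1,0
42031,Clarion,1,6,0
42033,Clearfield,1,4,0
42035,Clinton,1,5,1
42037,Columbia,1,3,1
42039,Crawford,1,4,0
42041,Cumberland,0,2,1
42043,Dauphin,0,2,1
42045,Delaware,0,1,0
42047,Elk,1,6,0
42049,Erie,1,2,0
42051,Fayette,1,1,0
42053,Forest,1,9,0
42055,Franklin,0,3,1
42057,Fulton,1,7,1
42059,Greene,1,6,0
42061,Huntingdon,1,5,1
42063,Indiana,1,4,0
42065,Jefferson,1,5,0
42067,Juniata,1,6,1
42069,Lackawanna,1,2,0
42071,Lancaster,0,2,1
42073,Lawrence,1,4,0
42075,Lebanon,0,3,1
42077,Lehigh,0,2,1
42079,Luzerne,1,2,1
42081,Lycoming,1,3,1
42083,McKean,1,5,0
42085,Mercer,1,2,0
42087,Mifflin,1,5,1
42089,Monroe,1,3,0
42091,Montgomery,0,1,0
42093,Montour,1,3,1
42095,Northampton,0,2,0
42097,Northumberland,1,4,1
42099,Perry,1,2,1
42101,Philadelphia,0,1,0
42103,Pike,1,1,0
42105,Potter,1,7,0
42107,Schuylkill,1,4,1
42109,Snyder,1,5,1
42111,Somerset,1,4,0
42113,Sullivan,1,8,0
42115,Susquehanna,1,6,0
42117,Tioga,1,6,0
42119,Union,1,5,1
42121,Venango,1,5,0
42123,Warren,1,5,0
42125,Washington,1,1,0
42127,Wayne,1,6,0
42129,Westmoreland,1,1,0
42131,Wyoming,1,2,0
42133,York,0,2,1
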