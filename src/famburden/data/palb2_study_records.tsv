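study	patient_id	gene	variant	consequence	protein_change	population	diagnosis	excluded	exclusion_reason
Hansford2015	P124	PALB2	c.1193AC>A	fs deletion	Val398fs	European	Diffuse gastric cancer (45)
Sahasrabudhe2017	CG-12	PALB2	c.1240C>T	Stop-site gain	Arg414Ter	European	Intestinal gastric cancer (69)
Sahasrabudhe2017	CG-008	PALB2	c.1240C>T	Stop-site gain	Arg414Ter	European	Diffuse gastric cancer (48)
Sahasrabudhe2017	GM037589	PALB2	c.1240C>T	Stop-site gain	Arg414Ter	European	Gastric cancer (46)
Sahasrabudhe2017	CG-05	PALB2	c.3201+1G>T	Splice-site variant	NA	European	Diffuse gastric cancer (50)
Sahasrabudhe2017	CG-039	PALB2	c.1882_1890delAAGTCCTGC	In-frame deletion	Lys628_Cys630del	European	Diffuse gastric cancer (47)
Sahasrabudhe2017	CG-028	PALB2	c.1882_1890delAAGTCCTGC	In-frame deletion	Lys628_Cys630del	Latin American	Intestinal gastric cancer (81)
Sahasrabudhe2017	3CG-103	PALB2	c.2753C>A	Missense	Pro918Gln	Latin American	Mixed (79)
Fewings2018	GST_172_301	PALB2	c.757_758TAG>T	fs deletion	Leu253fs	European	Diffuse gastric cancer (55)
Teixeira_unpub	GM048157	PALB2	c.1438A>T	Stop-site gain	Lys480Ter	European	Diffuse gastric cancer (56)	true	did not fit search criteria
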