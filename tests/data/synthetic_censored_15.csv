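study_id,d,n_treat,n_ctrl,subgroup,variance,se,z,p_two_sided,significant,imputed
sim0001,1.0923600312768333,7,13,,0.2496114807284979,0.49961132966386773,2.1864196554785087,0.02878491688754628,True,False
sim0002,0.66888791901413347,14,32,,0.10754173499599597,0.32793556531122997,2.0396931280671549,0.041380899798989498,True,False
sim0003,0.09806264854791126,21,29,,0.082197969070139584,0.28670188187408113,0.34203698945715388,0.73232305561551936,False,False
sim0004,0.50212181575454495,19,8,,0.18230058483360251,0.42696672567496696,1.176020953297402,0.23958650312390817,False,False
sim0005,-0.11626863186054129,21,51,,0.067320768497654754,0.25946246067139417,-0.44811350189033317,0.65407128417994098,False,False
sim0006,0.18478260814693459,27,14,,0.10888200617626191,0.32997273550440787,0.55999356390602828,0.57548382771145379,False,False
sim0007,0.050864325859847209,34,24,,0.07110073464535227,0.2666472100835714,0.19075513988653972,0.84871743640153685,False,False
sim0008,0.13290397406004742,35,28,,0.064425900526356772,0.25382257686493687,0.52360974229163149,0.60055000403938075,False,False
sim0009,0.84978242186535136,34,12,,0.12059433895781724,0.34726695632872595,2.4470581101328279,0.014402761569770977,True,False
sim0010,-0.18908323637896743,28,38,,0.062300927235542231,0.24960153692544088,-0.75754035294842348,0.44872619969500194,False,False
sim0011,0.3033307313985027,10,41,,0.12529229814372089,0.35396652121877414,0.8569475168275158,0.3914738905214179,False,False
sim0012,0.49449651106476583,21,20,,0.10060108175874549,0.31717673584099054,1.5590566872870228,0.1189829638139847,False,False
sim0013,0.082515646224631548,36,28,,0.063545257491062462,0.25208184680984558,0.32733672522986579,0.74341321833548768,False,False
sim0014,0.60889838014096831,25,43,,0.065981970110387589,0.25686955855139315,2.3704575332897728,0.01776608473975665,True,False
sim0015,-0.033452162039215208,31,26,,0.070729419180694669,0.26595003136058221,-0.12578363637739101,0.89990319516500439,False,False
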