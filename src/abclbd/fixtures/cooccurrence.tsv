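#window_size=8
#n_documents=0
C0003765	C0018790	2
C0003765	C0043194	189
C0003765	C0342895	395
C0007745	C0018790	2
C0007745	C0043194	43
C0007745	C0342895	50
C0008405	C0018790	2
C0008405	C0043194	90
C0008405	C0342895	481
C0017770	C0018790	2
C0017770	C0043194	6
C0017770	C0342895	6
C0018790	C0019602	2
C0018790	C0023401	2
C0018790	C0024360	2
C0018790	C0028375	2
C0018790	C0031716	2
C0018790	C0031951	2
C0018790	C0037906	2
C0018790	C0058624	2
C0018790	C0070662	2
C0018790	C0368608	2
C0018790	C0556150	2
C0018790	C2348386	2
C0018790	C2348388	2
C0019602	C0043194	508
C0019602	C0342895	158
C0023401	C0043194	139
C0023401	C0342895	411
C0024360	C0043194	28
C0024360	C0342895	12
C0028375	C0043194	2
C0028375	C0342895	4
C0031716	C0043194	35
C0031716	C0342895	15
C0037906	C0043194	29
C0037906	C0342895	55
C0043194	C0058624	2
C0043194	C0070662	2
C0043194	C0368608	6
C0043194	C0556150	23
C0058624	C0342895	19
C0342895	C0368608	29
C0342895	C0556150	503
C0342895	C2348386	3
C0342895	C2348388	17
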