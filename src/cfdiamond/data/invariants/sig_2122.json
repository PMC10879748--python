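{"signature":[2,1,2,2],"reduced":[["m",0],["m",1],["m",2],["m",3],["m",4],["m",5],["u1",6],["u2",6],["m",7],["m",8],["m",9],["m",10],["m",11],["m",12]],"provenance":"numeric-interpolation","max_degree":2,"polys":[[[1,1,[0]],[-3,1,[1,4]],[3,1,[1,8]],[-3,1,[2,5]]],[[1,1,[1]],[-1,2,[5]],[-3,2,[1,7]],[-1,1,[3,6]],[-1,2,[3,7]],[1,2,[5,6]],[1,1,[5,7]]],[[1,1,[2]],[1,1,[4]],[-1,1,[8]],[-2,1,[2,6]],[-1,1,[2,7]]],[[1,1,[3]],[-1,1,[5]],[-1,1,[3,6]],[-1,2,[3,7]],[1,2,[5,6]],[1,1,[5,7]]],[[1,1,[0,6]],[-2,1,[1,4]],[2,1,[1,8]],[-1,1,[2,3]]],[[1,1,[0,7]],[-2,1,[1,4]],[2,1,[1,8]],[2,1,[2,3]],[-3,1,[2,5]]],[[1,1,[1,2]],[-1,1,[1,4]],[1,1,[1,8]],[-1,1,[2,5]]],[[1,1,[1,6]],[-1,1,[1,7]],[-1,1,[3,6]],[-1,2,[3,7]],[1,2,[5,6]],[1,1,[5,7]]]],"checksum":"ccddd67ac0517b030b9fc4f784a4fcb8f0beb23617c89dccc2662d91d868b089"}
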